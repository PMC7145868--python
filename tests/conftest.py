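import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from topplekit import Frame

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def simple_frame():
    """Five particles in two residues inside a 10 nm cube."""
    return Frame(
        indices=[1, 2, 3, 4, 5],
        names=["BB", "SC1", "BB", "PO4", "GL0"],
        residue_names=["ALA", "ALA", "GLY", "POPE", "POPE"],
        residue_ids=[1, 1, 2, 3, 3],
        chains=["A", "A", "A", "", ""],
        positions=np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [2.0, 2.0, 2.0],
                            [5.0, 5.0, 7.0], [5.0, 5.0, 6.7]]),
        box=[10.0, 10.0, 10.0],
        time=0.0,
    )


def brute_force_contacts(frame, protein_sel, topo, cutoff):
    """O(N^2) all-pairs reference for lipid_contacts (test oracle)."""
    from topplekit.fingerprint import _headgroup_rows

    box = frame.box
    hg_rows, hg_labels = _headgroup_rows(frame, topo)
    prot_rows = protein_sel.rows(frame)
    out = set()
    for pr in prot_rows:
        for hr, (lip_rid, ltype) in zip(hg_rows, hg_labels):
            d = frame.positions[pr] - frame.positions[hr]
            d -= box * np.round(d / box)
            if np.sqrt((d ** 2).sum()) <= cutoff:
                out.add((int(frame.residue_ids[pr]), lip_rid, ltype))
    return out
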