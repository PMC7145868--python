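import numpy as np
import pytest

from topplekit import (DepletionEnrichmentAnalyzer, Frame, LipidTopologyMap,
                       Selection, de_index, group_binding_sites,
                       headgroup_density_map, lipid_contacts,
                       make_enriched_shell_frames, residue_contact_profile,
                       shell_census)
from topplekit.fingerprint import ShellCensus

from conftest import brute_force_contacts

BOX = [12.0, 12.0, 12.0]
TOPO = LipidTopologyMap({"POPE": "POPE", "CL": "CL"},
                        {"POPE": ["PO4", "GL0"], "CL": ["PO41", "PO42", "GL0"]},
                        {"POPE": ["PO4"], "CL": ["PO41", "PO42"]})


def _frame(protein_beads, lipid_beads, box=BOX):
    """protein_beads: [(resid, x, y, z)]; lipid_beads: [(resid, resname, bead, x, y, z)]."""
    indices, names, resnames, resids, positions = [], [], [], [], []
    pid = 1
    for rid, x, y, z in protein_beads:
        indices.append(pid); names.append("BB"); resnames.append("PRT")
        resids.append(rid); positions.append((x, y, z)); pid += 1
    for rid, resname, bead, x, y, z in lipid_beads:
        indices.append(pid); names.append(bead); resnames.append(resname)
        resids.append(rid); positions.append((x, y, z)); pid += 1
    fr = Frame(indices, names, resnames, resids, [""] * len(indices),
               np.asarray(positions), box)
    prot_sel = Selection("prot", [i + 1 for i in range(len(protein_beads))])
    return fr, prot_sel


class TestLipidContacts:
    def test_cutoff_boundary(self):
        fr, sel = _frame([(1, 5, 5, 5)], [(10, "POPE", "PO4", 5.69, 5, 5),
                                          (11, "POPE", "PO4", 5.71, 5, 5)])
        contacts = lipid_contacts(fr, sel, TOPO, cutoff=0.7)
        assert (1, 10, "POPE") in contacts
        assert all(lip != 11 for (_r, lip, _t) in contacts)

    def test_multiple_residue_beads_deduplicate(self):
        fr, sel = _frame([(1, 5.0, 5, 5), (1, 5.1, 5, 5), (1, 5.2, 5, 5)],
                         [(10, "POPE", "PO4", 5.4, 5, 5)])
        assert lipid_contacts(fr, sel, TOPO) == {(1, 10, "POPE")}

    def test_minimum_image_wrap(self):
        fr, sel = _frame([(1, 0.1, 5, 5)], [(10, "POPE", "PO4", 11.8, 5, 5)])
        assert lipid_contacts(fr, sel, TOPO) == {(1, 10, "POPE")}

    def test_no_headgroups_is_error(self):
        fr, sel = _frame([(1, 5, 5, 5)], [(10, "POPE", "C1A", 5.4, 5, 5)])
        with pytest.raises(ValueError, match="headgroup"):
            lipid_contacts(fr, sel, TOPO)

    def test_matches_brute_force_on_random_fixtures(self):
        # cell-list search must agree exactly with O(N^2) recomputation
        rng = np.random.default_rng(42)
        for trial in range(10):
            prot = [(rid, *rng.uniform(0, 12, 3)) for rid in range(1, 6)]
            lips = []
            for rid in range(10, 60):
                resname = "CL" if rid % 7 == 0 else "POPE"
                beads = TOPO.headgroup_beads[resname]
                base = rng.uniform(0, 12, 3)
                for b in beads:
                    lips.append((rid, resname, b, *(base + rng.uniform(-0.2, 0.2, 3))))
            fr, sel = _frame(prot, lips)
            assert lipid_contacts(fr, sel, TOPO) == brute_force_contacts(fr, sel, TOPO, 0.7)


class TestShellCensus:
    def test_constructed_counts(self):
        lips = [(10, "POPE", "PO4", 5.3, 5, 5), (11, "POPE", "PO4", 5, 5.3, 5),
                (12, "POPE", "PO4", 5, 5, 5.3), (13, "CL", "PO41", 4.7, 5, 5),
                (20, "POPE", "PO4", 9, 9, 9), (21, "CL", "PO41", 1, 1, 1)]
        fr, sel = _frame([(1, 5, 5, 5)], lips)
        census = shell_census([fr], sel, TOPO)
        assert census.frame_counts[0] == {"POPE": 3, "CL": 1}
        assert census.bulk_counts == {"POPE": 4, "CL": 2}

    def test_empty_shell(self):
        fr, sel = _frame([(1, 5, 5, 5)], [(10, "POPE", "PO4", 9, 9, 9)])
        census = shell_census([fr], sel, TOPO)
        assert census.frame_counts[0] == {"POPE": 0, "CL": 0}

    def test_cardiolipin_counted_once_via_both_headgroups(self):
        lips = [(10, "CL", "PO41", 5.4, 5, 5), (10, "CL", "PO42", 5, 5.4, 5)]
        fr, sel = _frame([(1, 5, 5, 5)], lips)
        census = shell_census([fr], sel, TOPO)
        assert census.frame_counts[0]["CL"] == 1
        assert census.bulk_counts["CL"] == 1


class TestDEIndex:
    def _census(self, frame_counts, bulk):
        return ShellCensus(frame_counts=frame_counts, bulk_counts=bulk, cutoff=0.7)

    def test_neutral_mixing_gives_unity(self):
        census = self._census([{"POPE": 70, "POPG": 25, "CL": 5}] * 3,
                              {"POPE": 700, "POPG": 250, "CL": 50})
        for r in de_index(census):
            assert r.de_index == pytest.approx(1.0)

    def test_enrichment_arithmetic(self):
        census = self._census([{"POPE": 60, "POPG": 30, "CL": 10}] * 5,
                              {"POPE": 700, "POPG": 250, "CL": 50})
        res = {r.lipid_type: r.de_index for r in de_index(census)}
        assert res["CL"] == pytest.approx(0.10 / 0.05)
        assert res["POPE"] == pytest.approx(0.60 / 0.70)

    def test_pooled_weighted_identity(self):
        # sum_L bulk_ratio(L) * DE(L) = 1 for the pooled estimator
        rng = np.random.default_rng(0)
        fcs = [{"POPE": int(rng.integers(0, 20)), "POPG": int(rng.integers(0, 10)),
                "CL": int(rng.integers(0, 5))} for _ in range(20)]
        fcs = [fc for fc in fcs if sum(fc.values())]
        bulk = {"POPE": 700, "POPG": 250, "CL": 50}
        res = de_index(self._census(fcs, bulk), estimator="pooled")
        total = sum(bulk.values())
        assert sum(bulk[r.lipid_type] / total * r.de_index for r in res) == pytest.approx(1.0)

    def test_frame_reorder_invariance(self):
        fcs = [{"POPE": 3, "CL": 1}, {"POPE": 1, "CL": 1}, {"POPE": 5, "CL": 0}]
        bulk = {"POPE": 90, "CL": 10}
        a = {r.lipid_type: r.de_index for r in de_index(self._census(fcs, bulk))}
        b = {r.lipid_type: r.de_index for r in de_index(self._census(fcs[::-1], bulk))}
        assert a == b

    def test_type_absent_from_bulk_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            de_index(self._census([{"POPE": 1, "CL": 0}], {"POPE": 10, "CL": 0}))

    def test_all_empty_shells_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            de_index(self._census([{"POPE": 0}] * 3, {"POPE": 10}))

    def test_null_generator_within_three_se_of_unity(self):
        comp = {"POPE": 0.70, "POPG": 0.25, "CL": 0.05}
        frames, topo, sel = make_enriched_shell_frames(comp, comp, n_shell=25,
                                                       n_bulk=975, n_frames=200, seed=3)
        ana = DepletionEnrichmentAnalyzer().fit(frames, sel, topo)
        for r in ana.results_:
            assert abs(r.de_index - 1.0) < 3 * r.se + 1e-9


class TestResidueContactProfile:
    def test_permanent_binding_full_occupancy(self):
        def frame():
            lips = [(50, "CL", "PO41", 5.4, 5, 5)]
            return _frame([(10, 5, 5, 5), (14, 5, 5.3, 5), (55, 5.2, 5, 5),
                           (99, 9, 9, 9)], lips)
        frames = [frame()[0] for _ in range(4)]
        sel = frame()[1]
        prof = residue_contact_profile(frames, sel, TOPO)
        assert prof.occupancy[(10, "CL")] == 1.0
        assert prof.occupancy[(14, "CL")] == 1.0
        assert (99, "CL") not in prof.occupancy

    def test_half_frame_binding(self):
        near, sel = _frame([(1, 5, 5, 5)], [(50, "POPE", "PO4", 5.4, 5, 5)])
        far, _ = _frame([(1, 5, 5, 5)], [(50, "POPE", "PO4", 9, 9, 9)])
        prof = residue_contact_profile([near, far, near, far], sel, TOPO)
        assert prof.occupancy[(1, "POPE")] == 0.5

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(1)
        frames = []
        for _ in range(3):
            prot = [(rid, *rng.uniform(4, 8, 3)) for rid in range(1, 5)]
            lips = [(rid, "POPE", "PO4", *rng.uniform(3, 9, 3)) for rid in range(10, 30)]
            fr, sel = _frame(prot, lips)
            frames.append(fr)
        prof = residue_contact_profile(frames, sel, TOPO)
        counts = {}
        for fr in frames:
            seen = {(r, t) for (r, _lip, t) in brute_force_contacts(fr, sel, TOPO, 0.7)}
            for key in seen:
                counts[key] = counts.get(key, 0) + 1
        assert prof.occupancy == {k: v / 3 for k, v in counts.items()}

    def test_binding_site_grouping(self):
        def frame():
            return _frame([(10, 5, 5, 5), (11, 5.3, 5, 5), (90, 1, 1, 1)],
                          [(50, "CL", "PO41", 5.15, 5.2, 5)])
        frames = [frame()[0] for _ in range(5)]
        sel = frame()[1]
        prof = residue_contact_profile(frames, sel, TOPO)
        sites = group_binding_sites(prof, "CL")
        assert sites == [{10, 11}]


class TestDensityMap:
    def test_point_mass_occupies_single_cell(self):
        fr, sel = _frame([(1, 5, 5, 5)], [(10, "POPE", "PO4", 3.05, 7.05, 5)])
        edges = np.arange(0, 12.1, 0.5)
        gm = headgroup_density_map([fr], TOPO, "POPE", edges, edges)
        # the PO4 and GL0 beads of other types absent; only one occupied cell
        assert (gm.values > 0).sum() == 1

    def test_absent_type_warns_and_zeroes(self, caplog):
        fr, _sel = _frame([(1, 5, 5, 5)], [(10, "POPE", "PO4", 3, 7, 5)])
        edges = np.arange(0, 12.1, 1.0)
        with caplog.at_level("WARNING"):
            gm = headgroup_density_map([fr], TOPO, "CL", edges, edges)
        assert np.all(gm.values == 0)
        assert "CL" in caplog.text

    def test_uniform_placement_is_flat(self):
        # chi-square against uniform occupancy over cells
        from scipy.stats import chi2

        rng = np.random.default_rng(9)
        frames = []
        for _ in range(20):
            lips = [(rid, "POPE", "PO4", *rng.uniform(0, 12, 3)) for rid in range(10, 210)]
            frames.append(_frame([(1, 50, 50, 50)], lips, box=[12, 12, 12])[0])
        edges = np.arange(0, 12.1, 2.0)
        gm = headgroup_density_map(frames, TOPO, "POPE", edges, edges)
        counts = gm.values * 4.0 * len(frames)  # back to raw counts (cell area 4)
        expected = counts.sum() / counts.size
        stat = ((counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.999, counts.size - 1)
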