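"""Noncovalent contact detection, water bridges, occurrence fingerprints."""

import numpy as np
import pytest

from confrec import interaction_fields as mif
from confrec.conformer_sampling import ConformerEnsemble
from confrec.structure_io import ResiduePositionMap
from tests.conftest import make_system


def two_sided(coords_rec, coords_lig, **kwargs):
    coords = np.vstack([coords_rec, coords_lig])
    n_r = len(coords_rec)
    segments = ["receptor"] * n_r + ["ligand"] * (len(coords) - n_r)
    return make_system(coords, segments=segments, **kwargs)


class TestHbond:
    def test_within_distance_detected(self):
        system = two_sided([[0, 0, 0.0]], [[2.9, 0, 0.0]], elements=["O", "O"])
        records = mif.detect_contacts(system, kind="hbond")
        assert len(records) == 1
        assert records[0].angle is None  # no hydrogens: flagged fallback

    def test_beyond_cutoff_ignored(self):
        system = two_sided([[0, 0, 0.0]], [[5.0, 0, 0.0]], elements=["O", "O"])
        assert mif.detect_contacts(system, kind="hbond") == []

    def test_angle_rule_applies_when_hydrogens_present(self):
        # donor O-H pointing at the acceptor: angle 180 -> accepted
        good = two_sided([[0, 0, 0], [0.96, 0, 0.0]], [[2.9, 0, 0.0]],
                         elements=["O", "H", "O"],
                         bonds=[(0, 1)])
        recs = mif.detect_contacts(good, kind="hbond")
        assert len(recs) == 1 and recs[0].angle == pytest.approx(180.0, abs=1e-6)
        # H pointing away: angle 0 -> rejected
        bad = two_sided([[0, 0, 0], [-0.96, 0, 0.0]], [[2.9, 0, 0.0]],
                        elements=["O", "H", "O"], bonds=[(0, 1)])
        assert mif.detect_contacts(bad, kind="hbond") == []

    def test_cutoff_inclusive(self):
        system = two_sided([[0, 0, 0.0]], [[3.5, 0, 0.0]], elements=["N", "O"])
        assert len(mif.detect_contacts(system, kind="hbond")) == 1


class TestHydrophobicAndVdw:
    def test_apolar_pair_detected(self):
        system = two_sided([[0, 0, 0.0]], [[3.9, 0, 0.0]], elements=["C", "C"])
        assert len(mif.detect_contacts(system, kind="hydrophobic")) == 1
        assert mif.detect_contacts(
            system, kind="hydrophobic",
            params=mif.InteractionParams(d_hydrophobic=3.0)) == []

    def test_carbon_bonded_to_oxygen_not_apolar(self):
        system = two_sided([[0, 0, 0], [1.4, 0, 0.0]], [[3.0, 0, 0.0]],
                           elements=["C", "O", "C"], bonds=[(0, 1)])
        recs = mif.detect_contacts(system, kind="hydrophobic")
        assert recs == []

    def test_vdw_uses_radius_sum_and_excludes_hbonds(self):
        system = two_sided([[0, 0, 0.0]], [[3.7, 0, 0.0]],
                           elements=["C", "C"], radii=[1.7, 1.7])
        recs = mif.detect_contacts(system, kind="vdw")
        assert len(recs) == 1  # 3.7 <= 1.1 * 3.4 = 3.74
        polar = two_sided([[0, 0, 0.0]], [[3.0, 0, 0.0]],
                          elements=["O", "O"], radii=[1.52, 1.52])
        assert mif.detect_contacts(polar, kind="vdw") == []  # already an hbond

    def test_unknown_kind_rejected(self, complex_system):
        with pytest.raises(ValueError, match="unknown interaction kind"):
            mif.detect_contacts(complex_system, kind="saltbridge")


class TestBruteForceEquivalence:
    def test_matches_exhaustive_pair_oracle_on_random_frames(self, complex_system):
        """Detection equals an independent all-pairs re-application of the
        same geometric rules on 50 random frames."""
        rng = np.random.default_rng(0)
        system = complex_system
        params = mif.InteractionParams()
        rec = system.atom_indices("receptor")
        lig = system.atom_indices("ligand")
        polar = system.is_polar
        apolar = system.is_apolar_carbon
        for _ in range(50):
            coords = system.coords + rng.normal(0, 0.4, size=system.coords.shape)
            for kind in ("hbond", "hydrophobic", "vdw"):
                got = {(r.receptor_atom, r.ligand_atom)
                       for r in mif.detect_contacts(system, coords, kind, params)}
                want = set()
                hb = set()
                for i in rec:
                    for j in lig:
                        d = float(np.linalg.norm(coords[i] - coords[j]))
                        if polar[i] and polar[j] and d <= params.d_hbond:
                            hb.add((int(i), int(j)))
                for i in rec:
                    for j in lig:
                        d = float(np.linalg.norm(coords[i] - coords[j]))
                        if kind == "hbond" and (int(i), int(j)) in hb:
                            want.add((int(i), int(j)))
                        elif (kind == "hydrophobic" and apolar[i] and apolar[j]
                              and d <= params.d_hydrophobic):
                            want.add((int(i), int(j)))
                        elif (kind == "vdw" and (int(i), int(j)) not in hb
                              and d <= params.vdw_scale
                              * (system.vdw_radius[i] + system.vdw_radius[j])):
                            want.add((int(i), int(j)))
                assert got == want

    def test_segment_swap_symmetry(self, complex_system):
        """Swapping receptor/ligand tags mirrors the records but the pair
        sets match."""
        swapped = complex_system.replace(segment=np.where(
            complex_system.segment == "receptor", "ligand",
            np.where(complex_system.segment == "ligand", "receptor",
                     complex_system.segment)))
        for kind in ("hbond", "hydrophobic", "vdw"):
            a = {(r.receptor_atom, r.ligand_atom)
                 for r in mif.detect_contacts(complex_system, kind=kind)}
            b = {(r.ligand_atom, r.receptor_atom)
                 for r in mif.detect_contacts(swapped, kind=kind)}
            assert a == b

    def test_enlarging_cutoff_never_removes_records(self, complex_system):
        small = mif.InteractionParams(d_hydrophobic=3.5)
        large = mif.InteractionParams(d_hydrophobic=4.5)
        a = {(r.receptor_atom, r.ligand_atom)
             for r in mif.detect_contacts(complex_system, kind="hydrophobic",
                                          params=small)}
        b = {(r.receptor_atom, r.ligand_atom)
             for r in mif.detect_contacts(complex_system, kind="hydrophobic",
                                          params=large)}
        assert a <= b


class TestWaterBridges:
    def test_no_waters_empty(self, complex_system):
        assert mif.detect_water_bridges(complex_system) == []

    def test_one_sided_water_not_reported(self):
        # water close to the receptor polar atom only
        coords = [[0, 0, 0.0], [20, 0, 0.0], [2.5, 0, 0.0]]
        system = make_system(coords, elements=["O", "O", "O"],
                             segments=["receptor", "ligand", "water"])
        assert mif.detect_water_bridges(system) == []

    def test_bridging_water_reported_per_triple(self):
        coords = [[0, 0, 0.0], [6.0, 0, 0.0], [3.0, 0, 0.0]]
        system = make_system(coords, elements=["O", "O", "O"],
                             segments=["receptor", "ligand", "water"])
        recs = mif.detect_water_bridges(system)
        assert len(recs) == 1
        assert recs[0].water == 2


class TestOccurrenceMatrix:
    def _setup(self, receptor_atom_frames):
        """Build records hitting receptor atom 0 in the given frames."""
        records = [
            mif.InteractionRecord(frame=f, kind="hbond", receptor_atom=0,
                                  ligand_atom=1, distance=3.0,
                                  midpoint=(0, 0, 0))
            for f in receptor_atom_frames
        ]
        system = make_system(np.array([[0, 0, 0], [3, 0, 0.0]]),
                             segments=["receptor", "ligand"])
        rp = ResiduePositionMap(labels=["RP1"], mapping={"RP1": ("A", 1)})
        return records, system, rp

    def test_always_present_is_100(self):
        records, system, rp = self._setup([0, 1, 2, 3])
        ens = ConformerEnsemble(members={0: np.arange(4)})
        occ = mif.occurrence_matrix(records, ens, rp, system, "hbond")
        assert occ.values[0, 0] == pytest.approx(100.0)

    def test_one_in_four_is_25(self):
        records, system, rp = self._setup([2])
        ens = ConformerEnsemble(members={0: np.arange(4)})
        occ = mif.occurrence_matrix(records, ens, rp, system, "hbond")
        assert occ.values[0, 0] == pytest.approx(25.0)

    def test_matches_per_frame_recount(self, complex_system, planted_trajectory):
        traj, truth = planted_trajectory
        # reuse the receptor trajectory's labels on complex reference coords
        system = complex_system
        rng = np.random.default_rng(1)
        records = []
        n_frames = 40
        for f in range(n_frames):
            coords = system.coords + rng.normal(0, 0.3, size=system.coords.shape)
            records += mif.detect_contacts(system, coords, "hbond", frame=f)
        keys = system.residue_keys("receptor")
        labels = [f"RP{i + 1}" for i in range(len(keys))]
        rp = ResiduePositionMap(labels=labels, mapping=dict(zip(labels, keys)))
        ens = ConformerEnsemble(members={0: np.arange(20), 1: np.arange(20, 40)})
        occ = mif.occurrence_matrix(records, ens, rp, system, "hbond")
        for c, frames in ((0, range(20)), (1, range(20, 40))):
            for row, lab in enumerate(occ.row_labels):
                key = rp.mapping[lab]
                hit = sum(
                    any(r.frame == f
                        and (str(system.chain_id[r.receptor_atom]),
                             int(system.residue_seq[r.receptor_atom])) == key
                        for r in records)
                    for f in frames
                )
                assert occ.values[row, c] == pytest.approx(100 * hit / 20)

    def test_unmapped_residue_goes_to_other_row(self):
        records, system, rp = self._setup([0])
        rp = ResiduePositionMap(labels=["RPX"], mapping={"RPX": ("A", 2)})
        ens = ConformerEnsemble(members={0: np.arange(2)})
        with pytest.warns(UserWarning, match="outside the position map"):
            occ = mif.occurrence_matrix(records, ens, rp, system, "hbond")
        assert "other" in occ.row_labels
        assert occ.values[occ.row_labels.index("other"), 0] == pytest.approx(50.0)


class TestPointCloud:
    def test_single_record_centroid(self):
        rec = mif.InteractionRecord(frame=0, kind="hbond", receptor_atom=0,
                                    ligand_atom=1, distance=3.0,
                                    midpoint=(1.0, 2.0, 3.0))
        cloud = mif.mif_point_cloud([rec], "hbond")
        assert np.allclose(cloud.centroid, [1, 2, 3])
        assert cloud.spread == 0.0

    def test_symmetric_records_centre_origin(self):
        recs = [
            mif.InteractionRecord(frame=0, kind="vdw", receptor_atom=0,
                                  ligand_atom=1, distance=3.0, midpoint=(1, 1, 1)),
            mif.InteractionRecord(frame=0, kind="vdw", receptor_atom=0,
                                  ligand_atom=2, distance=3.0,
                                  midpoint=(-1, -1, -1)),
        ]
        cloud = mif.mif_point_cloud(recs, "vdw")
        assert np.allclose(cloud.centroid, 0.0)

    def test_centroid_matches_mean_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        recs = [mif.InteractionRecord(frame=0, kind="hbond", receptor_atom=0,
                                      ligand_atom=1, distance=3.0,
                                      midpoint=tuple(p)) for p in pts]
        cloud = mif.mif_point_cloud(recs, "hbond")
        assert np.abs(cloud.centroid - pts.mean(axis=0)).max() < 1e-12

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty cloud"):
            cloud = mif.mif_point_cloud([], "hbond")
        assert cloud.points.shape == (0, 3)
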