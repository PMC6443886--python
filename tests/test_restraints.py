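import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triazofold.nmr_restraints import (
    DEFAULT_FORCE_CONSTANT,
    DistanceRestraint,
    RestraintSet,
    RoesyPeak,
    distances_to_restraints,
    peaks_to_distances,
    read_peak_table,
    read_restraint_table,
    restraint_energy,
    total_restraint_energy,
    write_peak_table,
    write_restraint_table,
)

PA = (1, "H_A")
PB = (7, "H_A")
PC = (2, "H_N")


def ref_peak(intensity=1000.0, r_ref=2.5):
    return RoesyPeak(PA, PB, intensity, is_reference=True, r_ref=r_ref)


class TestPeaksToDistances:
    def test_identity_intensity(self):
        peaks = [ref_peak(1000.0, 2.5), RoesyPeak(PA, PC, 1000.0)]
        out = dict(peaks_to_distances(peaks))
        assert out[(PA, PC)] == pytest.approx(2.5)
        assert out[(PA, PB)] == pytest.approx(2.5)  # reference maps to r_ref

    def test_sixty_fourth_intensity_doubles_distance(self):
        peaks = [ref_peak(1000.0, 2.5), RoesyPeak(PA, PC, 1000.0 / 64.0)]
        assert dict(peaks_to_distances(peaks))[(PA, PC)] == pytest.approx(5.0)

    def test_inverse_case(self):
        peaks = [ref_peak(1000.0, 3.0), RoesyPeak(PA, PC, 64_000.0)]
        assert dict(peaks_to_distances(peaks))[(PA, PC)] == pytest.approx(1.5)

    def test_missing_reference(self):
        with pytest.raises(ValueError, match="reference"):
            peaks_to_distances([RoesyPeak(PA, PC, 10.0)])

    def test_two_references(self):
        with pytest.raises(ValueError, match="reference"):
            peaks_to_distances([ref_peak(), ref_peak(2.0, 2.0)])

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            RoesyPeak(PA, PC, 0.0)
        with pytest.raises(ValueError, match="intensity"):
            RoesyPeak(PA, PC, -3.0)

    @given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_scale_covariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        base = [ref_peak(1234.5, 2.7)] + [
            RoesyPeak((1, "H_A"), (3 + i, "ring_H5"), float(rng.uniform(1, 1e4)))
            for i in range(4)
        ]
        scaled = [
            RoesyPeak(p.proton_a, p.proton_b, p.intensity * scale,
                      p.is_reference, p.r_ref)
            for p in base
        ]
        d1 = [d for _, d in peaks_to_distances(base)]
        d2 = [d for _, d in peaks_to_distances(scaled)]
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_monotone_in_intensity(self):
        peaks = [ref_peak()] + [
            RoesyPeak((1, "H_A"), (i, "H_N"), float(inten))
            for i, inten in zip(range(2, 8), (10, 100, 1000, 1e4, 1e5, 1e6))
        ]
        ds = [d for _, d in peaks_to_distances(peaks)][1:]
        assert all(b < a for a, b in zip(ds, ds[1:]))


class TestRestraintConstruction:
    def test_zero_slack(self):
        rset = distances_to_restraints([((PA, PB), 3.0)], slack=0.0)
        assert rset.restraints[0].r_upper == pytest.approx(3.0)

    def test_half_angstrom_slack(self):
        rset = distances_to_restraints([((PA, PB), 3.0)], slack=0.5)
        assert rset.restraints[0].r_upper == pytest.approx(3.5)

    def test_empty(self):
        assert len(distances_to_restraints([])) == 0

    def test_negative_slack(self):
        with pytest.raises(ValueError, match="slack"):
            distances_to_restraints([((PA, PB), 3.0)], slack=-0.1)

    def test_default_force_constant(self):
        rset = distances_to_restraints([((PA, PB), 3.0)])
        assert rset.restraints[0].k == 32.0 == DEFAULT_FORCE_CONSTANT

    def test_all_active(self):
        rset = distances_to_restraints([((PA, PB), 3.0), ((PA, PC), 2.0)])
        assert len(rset.active) == 2

    def test_duplicate_ids_rejected(self):
        r = DistanceRestraint(PA, PB, 3.0)
        with pytest.raises(ValueError, match="duplicate"):
            RestraintSet([r, DistanceRestraint(PA, PB, 4.0)])


class TestRestraintEnergy:
    def _conf_with_distance(self, heptamer, target):
        # scale an extended conformer is awkward; instead evaluate on a
        # conformer and pick r_upper relative to the actual distance
        from triazofold.foldamer_model import TorsionState, build_conformation

        return build_conformation(
            heptamer, TorsionState.uniform(heptamer, 180.0, 180.0)
        )

    def test_inside_flat_bottom(self, extended_heptamer):
        r = extended_heptamer.distance("1:H_A", "7:H_A")
        restr = DistanceRestraint(PA, PB, r + 0.3)
        assert restraint_energy(restr, extended_heptamer) == 0.0

    def test_one_angstrom_violation_is_32(self, extended_heptamer):
        r = extended_heptamer.distance("1:H_A", "7:H_A")
        restr = DistanceRestraint(PA, PB, r - 1.0, k=32.0)
        assert restraint_energy(restr, extended_heptamer) == pytest.approx(32.0)

    def test_half_angstrom_violation_is_8(self, extended_heptamer):
        r = extended_heptamer.distance("1:H_A", "7:H_A")
        restr = DistanceRestraint(PA, PB, r - 0.5, k=32.0)
        assert restraint_energy(restr, extended_heptamer) == pytest.approx(8.0)

    def test_energy_nondecreasing_beyond_bound(self, extended_heptamer):
        r = extended_heptamer.distance("1:H_A", "7:H_A")
        energies = [
            restraint_energy(DistanceRestraint(PA, PB, r - d), extended_heptamer)
            for d in np.linspace(0.0, 2.0, 30)
        ]
        assert all(b >= a for a, b in zip(energies, energies[1:]))

    def test_unresolvable_reference(self, extended_heptamer):
        restr = DistanceRestraint((99, "H_A"), PB, 3.0)
        with pytest.raises(LookupError, match="99"):
            restraint_energy(restr, extended_heptamer)

    def test_total_all_satisfied(self, extended_heptamer):
        rset = distances_to_restraints([((PA, PB), 50.0), ((PA, PC), 50.0)])
        total, pens = total_restraint_energy(rset, extended_heptamer)
        assert total == 0.0
        assert set(pens) == set(rset.active_ids)

    def test_total_additivity(self, extended_heptamer):
        r1 = extended_heptamer.distance("1:H_A", "7:H_A")
        r2 = extended_heptamer.distance("1:H_A", "2:H_N")
        rset = RestraintSet([
            DistanceRestraint(PA, PB, r1 - 0.5, k=32.0),
            DistanceRestraint(PA, PC, r2 - 0.5, k=32.0),
        ])
        total, _ = total_restraint_energy(rset, extended_heptamer)
        assert total == pytest.approx(16.0)

    def test_inactive_reported_but_excluded(self, extended_heptamer):
        r1 = extended_heptamer.distance("1:H_A", "7:H_A")
        r2 = extended_heptamer.distance("1:H_A", "2:H_N")
        active = DistanceRestraint(PA, PB, r1 - 0.5, k=32.0)
        inactive = DistanceRestraint(PA, PC, r2 - 1.25, k=32.0, active=False)
        rset = RestraintSet([active, inactive])
        total, pens = total_restraint_energy(rset, extended_heptamer)
        assert total == pytest.approx(8.0)
        assert pens[inactive.restraint_id] == pytest.approx(50.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DistanceRestraint(PA, PB, -1.0)
        with pytest.raises(ValueError):
            DistanceRestraint(PA, PB, 3.0, k=-1.0)


class TestTables:
    def test_peak_table_round_trip(self, tmp_path):
        peaks = [ref_peak(1000.0, 2.5), RoesyPeak(PA, PC, 123.4)]
        path = tmp_path / "peaks.tsv"
        write_peak_table(path, peaks)
        back = read_peak_table(path)
        assert len(back) == 2
        assert back[0].is_reference and back[0].r_ref == pytest.approx(2.5)
        assert back[1].intensity == pytest.approx(123.4)
        assert back[1].proton_a == PA and back[1].proton_b == PC

    def test_restraint_table_round_trip(self, tmp_path):
        rset = RestraintSet([
            DistanceRestraint(PA, PB, 3.25, k=32.0),
            DistanceRestraint(PA, PC, 4.0, k=16.0, active=False),
        ])
        path = tmp_path / "restraints.tsv"
        write_restraint_table(path, rset)
        back = read_restraint_table(path)
        assert len(back) == 2
        assert back.restraints[0].r_upper == pytest.approx(3.25)
        assert not back.restraints[1].active

    def test_peak_table_missing_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("res_a\trole_a\n1\tH_A\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_peak_table(path)


class TestInversion:
    def test_forward_model_inverse_at_zero_noise(self, heptamer):
        from triazofold.foldamer_model import TorsionState, build_conformation
        from triazofold.synthetic_data import forward_roesy, template_torsions

        conf = build_conformation(heptamer, template_torsions("helix", heptamer))
        peaks = forward_roesy(conf, sigma_log=0.0)
        recovered = peaks_to_distances(peaks)
        for (pa, pb), d in recovered:
            true = conf.distance(f"{pa[0]}:{pa[1]}", f"{pb[0]}:{pb[1]}")
            assert d == pytest.approx(true, rel=1e-12)
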