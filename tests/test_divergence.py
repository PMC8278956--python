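"""von Mises KDE, Hellinger distances, block baseline and structure painting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import i0, ive

from chiflip.divergence import (AngularDensity, block_baseline,
                                compare_simulations, hellinger, paint_structure,
                                records_to_frame, series_hellinger,
                                total_hellinger, vonmises_kde_1d,
                                vonmises_kde_2d)
from chiflip.series import DihedralSeries
from chiflip.synthetic import synthesize_residue_set


def grid_density(values: np.ndarray) -> AngularDensity:
    p = np.asarray(values, float)
    p = p / p.sum()
    centres = np.linspace(-180.0, 180.0, len(p), endpoint=False) + 180.0 / len(p)
    return AngularDensity(centres, p, kappa=0.0)


class TestVonMisesKDE1D:
    def test_point_mass_gives_centred_kernel(self):
        d = vonmises_kde_1d(np.array([-178.5]))  # first grid centre
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.p.argmax() == 0
        # kernel symmetry around the centre, including the wrap
        assert d.p[1] == pytest.approx(d.p[-1], rel=1e-9)

    def test_uniform_input_stays_uniform(self):
        centres = np.linspace(-180.0, 180.0, 120, endpoint=False)
        d = vonmises_kde_1d(centres)
        assert np.allclose(d.p, 1.0 / 120, atol=1e-12)

    def test_mass_conservation_random_input(self, rng):
        d = vonmises_kde_1d(rng.uniform(-180, 180, size=1000))
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_analytic_convolution_oracle(self, rng):
        # KDE of vM(0, 10) samples vs the exact vM(10) * vM(120) convolution,
        # whose Fourier coefficients are products of Bessel ratios
        kd, kk, bins = 10.0, 120.0, 120
        samples = np.degrees(rng.vonmises(0.0, kd, size=100_000))
        d = vonmises_kde_1d(samples, kappa=kk, bins=bins)
        theta = np.radians(d.centres_deg)
        f = np.ones_like(theta) / (2 * np.pi)
        for n in range(1, 60):
            rho = (ive(n, kd) / ive(0, kd)) * (ive(n, kk) / ive(0, kk))
            f += rho * np.cos(n * theta) / np.pi
        q = f / f.sum()
        assert 0.5 * np.abs(d.p - q).sum() < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vonmises_kde_1d(np.array([]))


class TestVonMisesKDE2D:
    def test_single_sample_product_kernel(self):
        d = vonmises_kde_2d(np.array([0.0]), np.array([0.0]))
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)
        i, j = np.unravel_index(d.p.argmax(), d.p.shape)
        assert abs(d.centres_deg[i]) < 3.0 and abs(d.centres_deg[j]) < 3.0
        # separable: joint equals outer product of its marginals
        outer = np.outer(d.marginal(0).p, d.marginal(1).p)
        assert np.allclose(d.p, outer, atol=1e-12)

    def test_marginal_matches_1d_estimate(self, rng):
        phi = np.degrees(rng.vonmises(1.0, 5.0, size=4000))
        psi = np.degrees(rng.vonmises(-1.0, 3.0, size=4000))
        d2 = vonmises_kde_2d(phi, psi)
        d1 = vonmises_kde_1d(phi)
        assert np.allclose(d2.marginal(0).p, d1.p, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vonmises_kde_2d(np.zeros(3), np.zeros(4))


class TestHellinger:
    def test_identity_is_zero(self, rng):
        p = grid_density(rng.uniform(0.1, 1.0, 120))
        assert hellinger(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        a = np.zeros(120)
        b = np.zeros(120)
        a[:60], b[60:] = 1.0, 1.0
        assert hellinger(grid_density(a), grid_density(b)) == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self):
        # exact vM(kappa=10) densities at 0 and 90 deg on the 120-bin grid
        # vs high-resolution numerical quadrature of the Bhattacharyya integral
        centres = np.radians(np.linspace(-180, 180, 120, endpoint=False) + 1.5)
        pa = np.exp(10.0 * np.cos(centres))
        pb = np.exp(10.0 * np.cos(centres - np.pi / 2))
        h = hellinger(grid_density(pa), grid_density(pb))
        f = lambda x: (np.sqrt(np.exp(10 * np.cos(x)) * np.exp(10 * np.cos(x - np.pi / 2)))
                       / (2 * np.pi * i0(10.0)))
        bc, _ = quad(f, -np.pi, np.pi, limit=200)
        assert abs(h - np.sqrt(1 - bc)) < 1e-3

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties_on_random_densities(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (grid_density(rng.gamma(0.5, size=60) + 1e-12) for _ in range(3))
        hpq, hqr, hpr = hellinger(p, q), hellinger(q, r), hellinger(p, r)
        assert hpq == hellinger(q, p)  # symmetry exact
        assert 0.0 <= hpq <= 1.0
        assert hpr <= hpq + hqr + 1e-12  # triangle inequality

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hellinger(grid_density(np.ones(120)), grid_density(np.ones(60)))


class TestTotalHellinger:
    @pytest.mark.parametrize("h1,h2,expected", [
        (0.0, 0.0, 0.0), (0.3, 0.4, 0.5), (0.7, 0.0, 0.7),
    ])
    def test_quadrature_combination(self, h1, h2, expected):
        assert total_hellinger(h1, h2) == pytest.approx(expected)


def _bundle(res, rng, n, chi1_shift=0.0, kinds=("phi", "psi", "chi1")):
    grid = dict(t0=0.0, dt=1.0, n=n)
    out = {}
    means = {"phi": -60.0, "psi": -45.0, "chi1": 300.0 + chi1_shift}
    for kind in kinds:
        ang = np.degrees(rng.vonmises(np.radians(means[kind]), 20.0, size=n))
        out[kind] = DihedralSeries(residue=res, kind=kind, angles=ang, **grid)
    return out


class TestBlockBaseline:
    def test_two_blocks_equal_single_pair(self, rng):
        data = {1: _bundle(1, rng, 400)}
        base = block_baseline(data, (0.0, 200.0, 400.0))
        blocks = {k: (s.angles[:200], s.angles[200:]) for k, s in data[1].items()}
        a = {k: DihedralSeries(t0=0, dt=1, n=200, residue=1, kind=k, angles=v[0])
             for k, v in blocks.items()}
        b = {k: DihedralSeries(t0=0, dt=1, n=200, residue=1, kind=k, angles=v[1])
             for k, v in blocks.items()}
        assert base.per_residue[1] == pytest.approx(series_hellinger(a, b)[2])

    def test_stationary_blocks_give_small_baseline(self, rng):
        data = {1: _bundle(1, rng, 40_000)}
        base = block_baseline(data, (0.0, 10_000.0, 20_000.0, 30_000.0, 40_000.0))
        assert base.per_residue[1] < 0.1

    def test_shifted_distribution_gives_large_baseline(self, rng):
        bundle = _bundle(1, rng, 400)
        ang = bundle["chi1"].angles.copy()
        ang[200:] = (ang[200:] + 120.0) % 360.0  # rotamer flip between blocks
        bundle["chi1"] = DihedralSeries(t0=0.0, dt=1.0, n=400, residue=1,
                                        kind="chi1", angles=ang)
        base = block_baseline({1: bundle}, (0.0, 200.0, 400.0))
        assert base.per_residue[1] > 0.9

    def test_baseline_decreases_with_sample_size(self, rng):
        # H_T between independent same-distribution samples shrinks with n
        prev = None
        for n in (100, 1000, 10_000, 100_000):
            a = _bundle(1, rng, n)
            b = _bundle(1, rng, n)
            ht = series_hellinger(a, b)[2]
            if prev is not None:
                assert ht < prev
            prev = ht

    def test_empty_block_rejected(self, rng):
        with pytest.raises(ValueError):
            block_baseline({1: _bundle(1, rng, 100)}, (0.0, 50.0, 100.0, 200.0))


class TestCompareSimulations:
    def test_self_comparison_never_significant(self, rng):
        data = {r: _bundle(r, rng, 400) for r in (1, 2, 3)}
        base = block_baseline(data, (0.0, 100.0, 200.0, 300.0, 400.0))
        recs = compare_simulations(data, data, base, exclusions=())
        assert all(r.h_total == 0.0 and not r.significant for r in recs)

    def test_only_shifted_residue_flagged(self, rng):
        a = {r: _bundle(r, rng, 2000) for r in (1, 2, 3)}
        b = {r: _bundle(r, rng, 2000) for r in (1, 2, 3)}
        b[2] = _bundle(2, rng, 2000, chi1_shift=120.0)
        base = block_baseline(a, (0.0, 500.0, 1000.0, 1500.0, 2000.0))
        recs = compare_simulations(a, b, base, exclusions=())
        flagged = {r.residue for r in recs if r.significant}
        assert flagged == {2}

    def test_excluded_residues_absent(self, rng):
        a = {r: _bundle(r, rng, 200) for r in (1, 202, 210, 217)}
        base = block_baseline(a, (0.0, 100.0, 200.0))
        recs = compare_simulations(a, a, base)  # default exclusion 202-217
        assert [r.residue for r in recs] == [1]

    def test_no_common_residues_rejected(self, rng):
        a = {1: _bundle(1, rng, 100)}
        b = {2: _bundle(2, rng, 100)}
        base = block_baseline(a, (0.0, 50.0, 100.0))
        with pytest.raises(ValueError):
            compare_simulations(a, b, base)


class TestPaintStructure:
    def _structure(self, tmp_path, resids=(1, 2, 3)):
        import MDAnalysis as mda

        n = len(resids) * 2
        u = mda.Universe.empty(n, n_residues=len(resids),
                               atom_resindex=np.repeat(range(len(resids)), 2),
                               trajectory=True)
        u.add_TopologyAttr("names", ["N", "CA"] * len(resids))
        u.add_TopologyAttr("resnames", ["ALA"] * len(resids))
        u.add_TopologyAttr("resids", list(resids))
        u.atoms.positions = np.arange(n * 3, dtype=np.float32).reshape(n, 3)
        path = tmp_path / "struct.pdb"
        u.atoms.write(str(path))
        return path

    def test_round_trip_b_factors(self, tmp_path, rng):
        import MDAnalysis as mda
        from chiflip.divergence import DivergenceRecord

        path = self._structure(tmp_path)
        recs = [DivergenceRecord(2, 0.3, 0.4, 0.5, 0.1, True)]
        out = paint_structure(recs, path, tmp_path / "painted.pdb")
        u = mda.Universe(str(out))
        res2 = u.select_atoms("resid 2")
        others = u.select_atoms("not resid 2")
        assert np.allclose(res2.tempfactors, 0.5, atol=5e-3)
        assert np.allclose(others.tempfactors, 0.0, atol=5e-3)

    def test_records_to_frame_columns(self, rng):
        from chiflip.divergence import DivergenceRecord

        df = records_to_frame([DivergenceRecord(1, 0.1, 0.2, 0.3, 0.05, True)])
        assert {"residue", "h_phipsi", "h_chi1", "h_total",
                "significant"} <= set(df.columns)


class TestEndToEndNull:
    def test_independent_realisations_not_flagged(self):
        # two realisations of the same (time-rescaled) composite process:
        # the 4-block baseline of the first absorbs all sampling noise
        a = synthesize_residue_set(500.0, 0.5, seed=101, rate_scale=200.0)
        b = synthesize_residue_set(500.0, 0.5, seed=102, rate_scale=200.0)
        base = block_baseline(a, (0.0, 125.0, 250.0, 375.0, 500.0))
        recs = compare_simulations(a, b, base, exclusions=())
        assert sum(r.significant for r in recs) == 0
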