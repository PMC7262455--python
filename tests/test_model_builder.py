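import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.stats import ks_2samp

import flexscatter as fs
from flexscatter.exceptions import (
    ArgumentError,
    SamplingFailureError,
    ValidationError,
)
from flexscatter.model_builder import LinkerSpec, sample_linker


def brute_force_linker(n_res, spec, rng):
    """Independent oracle sampler: draw every pseudo-angle first, build the
    walk, and reject the whole chain on any non-bonded clash.

    Uses its own rotation construction (Rodrigues) so it shares no
    geometry code with the production sampler.
    """
    lo, hi = spec.angle_bounds
    while True:
        thetas = rng.uniform(lo, hi, n_res)
        psis = rng.uniform(0.0, 2.0 * math.pi, n_res)
        pts = np.empty((n_res + 1, 3))
        pts[0] = 0.0
        u = np.array([0.0, 0.0, 1.0])
        for i in range(n_res):
            gamma = math.radians(180.0 - thetas[i])
            # Rodrigues rotation of u about a random perpendicular axis
            perp = np.cross(u, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(u, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            k = (math.cos(psis[i]) * perp
                 + math.sin(psis[i]) * np.cross(u, perp))
            v = (u * math.cos(gamma) + np.cross(k, u) * math.sin(gamma)
                 + k * np.dot(k, u) * (1.0 - math.cos(gamma)))
            pts[i + 1] = pts[i] + spec.bond_length * v
            u = v
        d = pdist(pts)
        # non-bonded pairs only: drop the n_res consecutive-bead distances
        m = len(pts)
        nonbond = np.ones(len(d), bool)
        idx = 0
        for a in range(m - 1):
            nonbond[idx] = False  # (a, a+1)
            idx += m - 1 - a
        if not np.any(d[nonbond] < spec.clash_radius):
            return pts[1:]


class TestSampleLinker:
    def test_zero_residues_gives_empty_trace(self):
        pts = sample_linker(np.zeros(3), [0, 0, 1], 0, LinkerSpec(1, 1),
                            np.random.default_rng(0))
        assert pts.shape == (0, 3)

    def test_bond_lengths_exact(self):
        rng = np.random.default_rng(1)
        spec = LinkerSpec(1, 30)
        pts = sample_linker(np.zeros(3), [0, 0, 1], 30, spec, rng)
        full = np.vstack([[0, 0, 0], pts])
        d = np.linalg.norm(np.diff(full, axis=0), axis=1)
        assert np.allclose(d, 3.8, atol=1e-6)

    def test_pseudo_angles_within_bounds(self):
        rng = np.random.default_rng(2)
        spec = LinkerSpec(1, 40, angle_bounds=(80.0, 140.0))
        pts = np.vstack([[0, 0, 0],
                         sample_linker(np.zeros(3), [0, 0, 1], 40, spec, rng)])
        v = np.diff(pts, axis=0)
        cosang = np.sum(-v[:-1] * v[1:], axis=1) / 3.8**2
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert ang.min() >= 80.0 - 1e-6 and ang.max() <= 140.0 + 1e-6

    def test_self_avoidance_respected(self):
        rng = np.random.default_rng(3)
        spec = LinkerSpec(1, 50)
        pts = sample_linker(np.zeros(3), [0, 0, 1], 50, spec, rng)
        d = pdist(pts)
        n = len(pts)
        nonbond = np.ones(len(d), bool)
        idx = 0
        for a in range(n - 1):
            nonbond[idx] = False
            idx += n - 1 - a
        assert d[nonbond].min() >= spec.clash_radius

    def test_statistics_match_brute_force_oracle(self):
        """End-to-end distances agree with an independent rejection
        sampler using identical rules (mean within 10%, KS p > 0.01)."""
        spec = LinkerSpec(1, 20)
        n = 10000
        rng1 = np.random.default_rng(10)
        rng2 = np.random.default_rng(20)
        e2e_main = np.array([
            np.linalg.norm(sample_linker(np.zeros(3), [0, 0, 1], 20, spec,
                                         rng1)[-1])
            for _ in range(n)])
        e2e_oracle = np.array([
            np.linalg.norm(brute_force_linker(20, spec, rng2)[-1])
            for _ in range(n)])
        assert abs(e2e_main.mean() - e2e_oracle.mean()) \
            < 0.10 * e2e_oracle.mean()
        assert ks_2samp(e2e_main, e2e_oracle).pvalue > 0.01


class TestAssembleConformer:
    def test_covers_full_chain_exactly_once(self, one_conformer):
        assert len(one_conformer) == 414
        assert np.array_equal(one_conformer.resid, np.arange(1, 415))

    def test_rigid_domains_superpose_on_source(self, one_conformer):
        layout = fs.default_layout()
        for dom in layout.domains:
            block = one_conformer.residue_slice(dom.start, dom.end)
            src = dom.coords - dom.coords.mean(axis=0)
            blk = block - block.mean(axis=0)
            # optimal rotation via Kabsch; internal RMSD must vanish
            H = src.T @ blk
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1, 1, d]) @ U.T
            rmsd = np.sqrt(np.mean(np.sum((blk - src @ R.T) ** 2, axis=1)))
            assert rmsd < 1e-6

    def test_interdomain_clash_radius_respected(self, one_conformer):
        layout = fs.default_layout()
        doms = layout.domains
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                a = one_conformer.residue_slice(doms[i].start, doms[i].end)
                b = one_conformer.residue_slice(doms[j].start, doms[j].end)
                assert cdist(a, b).min() >= 3.0

    def test_layout_tiling_validated(self):
        with pytest.raises(ValidationError):
            fs.ChainLayout(segments=(
                fs.DomainDefinition("A", 1, 10,
                                    fs.model_builder.synthetic_globule(10)),
                fs.LinkerSpec(12, 20),  # gap at residue 11
            ))


class TestGeneratePool:
    def test_pool_size(self):
        pool = fs.generate_pool(10, seed=3)
        assert len(pool) == 10

    def test_same_seed_bitwise_identical(self):
        p1 = fs.generate_pool(5, seed=11)
        p2 = fs.generate_pool(5, seed=11)
        for a, b in zip(p1.conformers, p2.conformers):
            assert np.array_equal(a.coords, b.coords)

    def test_pool_spans_compact_to_extended(self, small_pool):
        rgs = np.array([c.Rg for c in small_pool.conformers])
        assert rgs.std() / rgs.mean() > 0.10


@pytest.fixture(scope="module")
def ranked(small_pool):
    q = fs.default_qgrid(120)
    region = np.array([fs.coords_metrics(c, residue_range=(1, 258))[0]
                       for c in small_pool.conformers])
    gi = int(np.argsort(region)[3])
    data, _ = fs.make_flexible_dataset(
        conformer=small_pool.conformers[gi], qgrid=q,
        noise=fs.NoiseModel(seed=9))
    ranked_pool, report = fs.rank_pool(small_pool, data, k=5)
    return gi, data, ranked_pool, report


class TestRankPool:

    def test_generating_conformer_ranks_first(self, ranked):
        gi, _, _, report = ranked
        assert int(report["table"].iloc[0].id) == gi

    def test_sorted_scores_and_topk_bottomk(self, ranked):
        _, _, pool, report = ranked
        assert np.all(np.diff(pool.scores) >= 0)
        assert report["top"].chi2.max() <= report["bottom"].chi2.min()

    def test_permutation_invariance(self, ranked, small_pool):
        gi, data, ranked_pool, _ = ranked
        perm = np.random.default_rng(0).permutation(len(small_pool))
        shuffled = fs.Pool(
            conformers=[small_pool.conformers[i] for i in perm])
        r2, _ = fs.rank_pool(shuffled, data, k=5)
        assert np.allclose(r2.scores, ranked_pool.scores, rtol=1e-9)

    def test_k_exceeding_pool_rejected(self, small_pool):
        q = fs.default_qgrid(50)
        data, _ = fs.make_flexible_dataset(
            conformer=small_pool.conformers[0], qgrid=q,
            noise=fs.NoiseModel(seed=1))
        with pytest.raises(ArgumentError):
            fs.rank_pool(small_pool, data, k=len(small_pool) + 1)


class TestBuildDimer:
    def test_residue_count_doubles(self, one_conformer):
        dim = fs.build_dimer(one_conformer)
        assert len(dim) == 2 * len(one_conformer) == 828

    def test_dimer_rg_exceeds_monomer(self, one_conformer):
        rg_m, _ = fs.coords_metrics(one_conformer)
        rg_d, _ = fs.coords_metrics(fs.build_dimer(one_conformer))
        assert rg_d > rg_m

    def test_dimer_fits_monomer_data_worse(self, one_conformer):
        q = fs.default_qgrid(100)
        data, _ = fs.make_flexible_dataset(conformer=one_conformer,
                                           qgrid=q,
                                           noise=fs.NoiseModel(seed=3))
        mono = fs.debye_profile(fs.BeadModel.from_conformer(one_conformer), q)
        dim = fs.debye_profile(fs.build_dimer(one_conformer), q)
        assert fs.chi2_fit(dim, data).chi2 > fs.chi2_fit(mono, data).chi2
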