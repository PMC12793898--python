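from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimsap import plasticity
from epimsap._spearman import spearman
from epimsap.errors import AnalysisError
from epimsap.types import OrdinationResult, PhenotypeTable, SampleMetadata


def build_inputs(n_sites=3, per_group=3, pheno_fn=None, seed=0):
    """Deterministic ordination + phenotypes over site x season groups."""
    rng = np.random.default_rng(seed)
    rows, coords, righting = [], [], []
    i = 0
    for s in range(n_sites):
        for season in ("DRY", "WET"):
            center = rng.normal(size=2) * (s + 1 + (season == "WET") * 2)
            for _ in range(per_group):
                rows.append({"sample_id": f"S{i:02d}", "site": f"SITE{s}",
                             "season": season, "status": "NONE"})
                coords.append(center + rng.normal(scale=0.01, size=2))
                righting.append(10.0 + s + 3 * (season == "WET") + rng.normal(scale=0.01))
                i += 1
    meta = SampleMetadata(pd.DataFrame(rows))
    coords = np.array(coords)
    ordn = OrdinationResult("PCOA", [r["sample_id"] for r in rows],
                            coords - coords.mean(axis=0), np.ones(2), np.ones(2) / 2)
    if pheno_fn is not None:
        righting = pheno_fn(ordn, meta)
    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": [r["sample_id"] for r in rows],
        "righting_time": righting,
        "test_diameter": 50.0 + np.arange(i),
    }))
    return ordn, pheno, meta


def pheno_proportional_to_epi(scale):
    """Construct righting times whose group log-means track epi distances."""
    def fn(ordn, meta):
        groups = meta.factor("site:season", ordn.samples)
        # group mean log-righting proportional to centroid norm => pheno
        # pairwise distances monotone in epi pairwise distances along axis 1
        vals = np.empty(len(groups))
        for g in pd.unique(groups):
            m = groups == g
            vals[m] = np.expm1(scale * ordn.coordinates[m, 0].mean())
        return np.clip(vals, 1e-3, None)
    return fn


class TestCoupling:
    def test_monotone_phenotype_gives_rho_one(self):
        ordn, pheno, meta = build_inputs()
        groups = meta.factor("site:season", ordn.samples)
        # phenotype distance = 2 x epi distance by construction: set group
        # log-mean to 2 x (axis-1 coordinate), zero other axes
        ordn.coordinates[:, 1] = 0.0
        log_mean = {g: 2.0 * ordn.coordinates[groups == g, 0].mean() for g in set(groups)}
        righting = np.expm1(np.array([log_mean[g] for g in groups]) + 5.0)
        pheno = PhenotypeTable(pd.DataFrame({
            "sample_id": ordn.samples, "righting_time": righting,
            "test_diameter": np.full(len(groups), 50.0)}))
        res = plasticity.coupling(ordn, pheno, meta, pairing="ALL_PAIRS")
        assert res.rho == pytest.approx(1.0)

    def test_reverse_ranked_phenotype_gives_rho_minus_one(self):
        # three groups on one axis: epi centroid distances (1, 3, 2) for
        # the sorted pairs; group log-righting means (0, 5, 0.1) make the
        # phenotype distances (5, 0.1, 4.9) — exactly reverse-ranked
        rows, coords, righting = [], [], []
        centroid = {"SITE0": 0.0, "SITE1": 1.0, "SITE2": 3.0}
        log_mean = {"SITE0": 0.0, "SITE1": 5.0, "SITE2": 0.1}
        i = 0
        for site in centroid:
            for _ in range(2):
                rows.append({"sample_id": f"S{i}", "site": site,
                             "season": "DRY", "status": "NONE"})
                coords.append([centroid[site]])
                righting.append(float(np.expm1(log_mean[site])) + 1e-6)
                i += 1
        meta = SampleMetadata(pd.DataFrame(rows))
        ordn = OrdinationResult("PCOA", [r["sample_id"] for r in rows],
                                np.array(coords, float), np.ones(1), np.ones(1))
        pheno = PhenotypeTable(pd.DataFrame({
            "sample_id": ordn.samples, "righting_time": righting,
            "test_diameter": np.full(i, 50.0)}))
        res = plasticity.coupling(ordn, pheno, meta, pairing="ALL_PAIRS")
        assert res.rho == pytest.approx(-1.0)

    def test_too_few_pairs_flagged_not_nan_silent(self):
        ordn, pheno, meta = build_inputs(n_sites=1)
        res = plasticity.coupling(ordn, pheno, meta, pairing="WITHIN_SITE_ACROSS_SEASON")
        assert not res.defined and res.n_pairs == 1

    def test_rho_invariant_under_monotone_transform_of_axes(self):
        ordn, pheno, meta = build_inputs(seed=3)
        res1 = plasticity.coupling(ordn, pheno, meta, pairing="ALL_PAIRS")
        scaled = OrdinationResult("PCOA", ordn.samples, ordn.coordinates * 7.5,
                                  ordn.eigenvalues, ordn.explained)
        res2 = plasticity.coupling(scaled, pheno, meta, pairing="ALL_PAIRS")
        assert res1.rho == pytest.approx(res2.rho)

    def test_group_with_single_sample_rejected(self):
        ordn, pheno, meta = build_inputs(per_group=1)
        with pytest.raises(AnalysisError):
            plasticity.coupling(ordn, pheno, meta)

    def test_n_axes_restriction_changes_distances(self):
        ordn, pheno, meta = build_inputs(seed=5)
        full = plasticity.coupling(ordn, pheno, meta, pairing="ALL_PAIRS")
        one = plasticity.coupling(ordn, pheno, meta, pairing="ALL_PAIRS", n_axes=1)
        assert (full.pairs["epi_distance"] >= one.pairs["epi_distance"] - 1e-12).all()


class TestExactSpearman:
    def test_exhaustive_oracle_n5_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 20.0, 40.0, 35.0]
        rho, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho_oracle) - 1e-12
            for perm in permutations(range(5)))
        assert rho == pytest.approx(rho_oracle)
        assert p == pytest.approx(count / factorial(5))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
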