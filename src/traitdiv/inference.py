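"""Habitat contrasts, assembly tests, decoupling correlations, spatial checks.

Per landscape, forest and agroforestry sites are compared on five metrics —
species richness, the Jost-corrected Simpson index (D_eq), and the
standardized effect sizes of FD, FEve and Rao — using two-sample permutation
t tests (difference in group means; exhaustive enumeration when feasible,
Monte-Carlo with the add-one rule otherwise).  Assembly processes are tested
per habitat with one-sample t tests of mean SES against 0.  Because each
landscape contributes 15 SES comparisons (5 subgroups x 3 indices) sharing
the same data, only p < 0.01 is treated as conclusive; p < 0.05 and p < 0.10
are annotated as suggestive tiers without any formal FDR correction.

Spearman rank correlations between taxonomic (S, D_eq) and functional (SES)
metrics probe whether the functional signal is decoupled from richness, and
Moran's I (inverse-distance weights, row-normalized) checks residual spatial
autocorrelation of every metric across sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .distance import gower, pcoa_cailliez
from .indices import community_profiles
from .null_models import ses_table
from .traits import SUBGROUPS, CommunityMatrix, TraitTable, ValidationError

logger = logging.getLogger(__name__)

CONTRAST_METRICS = ("richness", "D_eq", "sesFD", "sesFEve", "sesRao")
FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class PermutationTestResult:
    mean_diff: float
    p_value: float
    exhaustive: bool
    n_iter: int


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_iter: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> PermutationTestResult:
    """Two-sided permutation test on the difference in group means.

    When the number of distinct group relabelings C(n1+n2, n1) does not
    exceed ``n_iter`` the test is exhaustive; otherwise ``n_iter`` random
    relabelings are drawn and the observed arrangement is included in both
    numerator and denominator (add-one rule), so Monte-Carlo p-values are
    never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("permutation test needs >= 2 values per group")
    obs = float(x.mean() - y.mean())
    if np.ptp(np.concatenate([x, y])) == 0:
        return PermutationTestResult(0.0, 1.0, True, 1)
    exhaustive = comb(len(x) + len(y), len(x)) <= n_iter
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = stats.permutation_test(
        (x, y),
        lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_iter,
        vectorized=True,
        rng=rng,
    )
    return PermutationTestResult(obs, float(res.pvalue), exhaustive, n_iter)


def one_sample_t(x: Sequence[float], mu: float = 0.0) -> tuple[float, float]:
    """One-sample t test of mean(x) against ``mu``; (nan, nan) if degenerate."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2 or np.std(x, ddof=1) == 0:
        logger.warning("one-sample t undefined (n < 2 or sd = 0); returning missing")
        return float("nan"), float("nan")
    res = stats.ttest_1samp(x, popmean=mu)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman needs paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman undefined for a constant vector; returning missing")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MoranResult:
    observed: float
    expected: float
    sd: float
    p_value: float


def morans_i(values: Sequence[float], coords: np.ndarray) -> MoranResult:
    """Moran's I with inverse-distance, row-normalized weights.

    E[I] = -1/(n-1); the p-value is two-sided from a normal approximation
    with the randomization variance (kurtosis-adjusted).  Coincident sites
    produce infinite weights and must be jittered or excluded by the caller.
    """
    x = np.asarray(values, dtype=float)
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(x)
    if n < 3:
        raise ValidationError("Moran's I needs at least 3 sites")
    dist = cdist(pts, pts)
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0):
        raise ValidationError(
            "coincident site coordinates give infinite spatial weights; "
            "jitter or exclude duplicated sites"
        )
    w = np.zeros((n, n))
    w[off] = 1.0 / dist[off]
    w /= w.sum(axis=1, keepdims=True)

    ei = -1.0 / (n - 1)
    s0 = w.sum()
    z = x - x.mean()
    v = float(z @ z)
    if v == 0:
        raise ValidationError("Moran's I undefined for constant values")
    obs = (n / s0) * float(z @ w @ z) / v
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    k = (float((z ** 4).sum()) / n) / (v / n) ** 2
    var = (
        n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
        - k * (n * (n - 1) * s1 - 2 * n * s2 + 6 * s0 * s0)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - ei * ei
    sd = float(np.sqrt(var))
    pv = stats.norm.cdf(obs, loc=ei, scale=sd)
    pv = 2 * pv if obs <= ei else 2 * (1 - pv)
    return MoranResult(obs, ei, sd, float(min(pv, 1.0)))


@dataclass(frozen=True)
class PipelineConfig:
    """Seeds, replicate counts and thresholds for a full analysis run."""

    subgroups: tuple[str, ...] = SUBGROUPS
    index_names: tuple[str, ...] = ("FD", "FEve", "Rao")
    n_null: int = 999
    n_iter: int = 100_000
    seed: int = 0
    alpha_conclusive: float = 0.01
    alpha_tiers: tuple[float, ...] = (0.01, 0.05, 0.10)
    shuffle_within_subgroup: bool = False


@dataclass
class PipelineResult:
    """All tables produced by :func:`run_pipeline`."""

    profiles: pd.DataFrame
    ses: pd.DataFrame
    contrasts: pd.DataFrame
    assembly: pd.DataFrame
    correlations: pd.DataFrame
    moran: pd.DataFrame
    config: PipelineConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("profiles", "ses", "contrasts", "assembly", "correlations", "moran"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       float_format=FLOAT_FORMAT)


def _metric_frame(profiles: pd.DataFrame, ses: pd.DataFrame) -> pd.DataFrame:
    """Wide per-site x subgroup frame of the five contrast metrics."""
    wide = ses.pivot_table(
        index=["site_id", "landscape", "habitat", "subgroup"],
        columns="index", values="ses", dropna=False,
    ).rename(columns={i: f"ses{i}" for i in ("FD", "FEve", "Rao")}).reset_index()
    prof = profiles[["site_id", "landscape", "habitat", "subgroup", "S", "D_eq"]]
    prof = prof.rename(columns={"S": "richness"})
    return prof.merge(wide, on=["site_id", "landscape", "habitat", "subgroup"], how="left")


def run_pipeline(
    community: CommunityMatrix,
    traits: TraitTable,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Full analysis: indices, SES, habitat contrasts, assembly and spatial tests.

    Deterministic for a fixed config: every RNG stream derives from
    ``config.seed`` via stable spawn keys, and rerunning with the same
    inputs reproduces every output table exactly.
    """
    community.check_against(traits)
    d = gower(traits)
    space = pcoa_cailliez(d)
    profiles = community_profiles(community, traits, d, space, config.subgroups)
    ses = ses_table(
        community, traits,
        subgroups=config.subgroups, index_names=config.index_names,
        n_null=config.n_null, seed=config.seed, d=d, space=space,
        shuffle_within_subgroup=config.shuffle_within_subgroup,
    )
    metrics = _metric_frame(profiles, ses)

    ss = np.random.SeedSequence(config.seed, spawn_key=(2**31,))
    perm_rng = np.random.default_rng(ss)

    contrast_rows, assembly_rows, corr_rows, moran_rows = [], [], [], []
    for landscape in sorted(metrics["landscape"].unique()):
        lm = metrics[metrics["landscape"] == landscape]
        for g in config.subgroups:
            gm = lm[lm["subgroup"] == g]
            for metric in CONTRAST_METRICS:
                if metric not in gm.columns:
                    continue
                fx = gm.loc[gm["habitat"] == "forest", metric].dropna().to_numpy()
                ax = gm.loc[gm["habitat"] == "agroforestry", metric].dropna().to_numpy()
                n_dropped = gm[metric].isna().sum()
                if n_dropped:
                    logger.info(
                        "%s/%s/%s: %d site(s) excluded pairwise (undefined metric)",
                        landscape, g, metric, n_dropped,
                    )
                rec = {
                    "landscape": landscape, "subgroup": g, "metric": metric,
                    "mean_forest": fx.mean() if len(fx) else np.nan,
                    "sd_forest": fx.std(ddof=1) if len(fx) > 1 else np.nan,
                    "n_forest": len(fx),
                    "mean_agroforestry": ax.mean() if len(ax) else np.nan,
                    "sd_agroforestry": ax.std(ddof=1) if len(ax) > 1 else np.nan,
                    "n_agroforestry": len(ax),
                }
                if len(fx) >= 2 and len(ax) >= 2:
                    pt = permutation_t_test(fx, ax, config.n_iter, perm_rng)
                    rec.update(mean_diff=pt.mean_diff, perm_p=pt.p_value,
                               exhaustive=pt.exhaustive)
                else:
                    rec.update(mean_diff=np.nan, perm_p=np.nan, exhaustive=False)
                p = rec["perm_p"]
                rec["significant"] = bool(p < config.alpha_conclusive) if p == p else False
                rec["suggestive_05"] = bool(p < 0.05) if p == p else False
                rec["suggestive_10"] = bool(p < 0.10) if p == p else False
                contrast_rows.append(rec)

                if metric.startswith("ses"):
                    for habitat in ("forest", "agroforestry"):
                        vals = gm.loc[gm["habitat"] == habitat, metric].dropna().to_numpy()
                        t, p1 = one_sample_t(vals) if len(vals) >= 2 else (np.nan, np.nan)
                        assembly_rows.append({
                            "landscape": landscape, "habitat": habitat,
                            "subgroup": g, "metric": metric, "n": len(vals),
                            "mean_ses": vals.mean() if len(vals) else np.nan,
                            "sd_ses": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                            "t": t, "p": p1,
                            "significant": bool(p1 < config.alpha_conclusive) if p1 == p1 else False,
                        })

            # decoupling: taxonomic vs functional metrics, per habitat
            for habitat in ("forest", "agroforestry"):
                hm = gm[gm["habitat"] == habitat]
                for tax in ("richness", "D_eq"):
                    for func in ("sesFD", "sesFEve", "sesRao"):
                        sub = hm[[tax, func]].dropna()
                        if len(sub) < 3 or sub[tax].nunique() < 2 or sub[func].nunique() < 2:
                            rho, p2 = np.nan, np.nan
                        else:
                            rho, p2 = spearman(sub[tax], sub[func])
                        corr_rows.append({
                            "landscape": landscape, "habitat": habitat, "subgroup": g,
                            "taxonomic": tax, "functional": func, "n": len(sub),
                            "rho": rho, "p": p2,
                        })

            # spatial autocorrelation per metric across the landscape's sites
            coords_df = community.meta.loc[
                community.meta["landscape"] == landscape, ["coord_x", "coord_y"]
            ]
            for metric in CONTRAST_METRICS:
                sub = gm.set_index("site_id")[metric].dropna()
                if len(sub) < 4 or sub.nunique() < 2:
                    continue
                try:
                    mi = morans_i(sub.to_numpy(), coords_df.loc[sub.index].to_numpy())
                except ValidationError as e:
                    logger.warning("Moran's I skipped for %s/%s/%s: %s",
                                   landscape, g, metric, e)
                    continue
                moran_rows.append({
                    "landscape": landscape, "subgroup": g, "metric": metric,
                    "n": len(sub), "I": mi.observed, "expected": mi.expected,
                    "sd": mi.sd, "p": mi.p_value,
                })

    return PipelineResult(
        profiles=profiles,
        ses=ses,
        contrasts=pd.DataFrame(contrast_rows),
        assembly=pd.DataFrame(assembly_rows),
        correlations=pd.DataFrame(corr_rows),
        moran=pd.DataFrame(moran_rows),
        config=config,
    )
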