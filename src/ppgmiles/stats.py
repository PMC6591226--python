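"""Per-feature group comparison between cohorts (subject-level).

Subjects — not beats or recordings — are the statistical unit: beat
feature values are first collapsed to a per-subject median over all
qualified beats of all of that subject's recordings, which avoids
pseudo-replication from the hundreds of correlated beats each person
contributes.  Each of the 42 features is then compared between groups
with a two-sided Mann-Whitney U test (exact enumeration for two small
groups, normal approximation with tie correction otherwise), reported
with Cliff's delta as the effect size and Bonferroni correction over the
42 tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .morphometry import FEATURE_CATALOG, FEATURE_IDS, N_FEATURES, RecordingBag

__all__ = [
    "FeatureComparison",
    "subject_feature_summary",
    "compare_feature_groups",
    "volcano_table",
]

ALPHA = 0.05
EXACT_MAX_N = 8


@dataclass
class FeatureComparison:
    """One feature's between-group test result."""

    feature_id: str
    name: str
    n_healthy: int
    n_ohcm: int
    median_healthy: float
    median_ohcm: float
    effect_size: float        # Cliff's delta, oHCM vs healthy, in [-1, 1]
    raw_p: float
    adjusted_p: float         # Bonferroni over the 42 catalog tests
    significant: bool


def subject_feature_summary(bags: list[RecordingBag]) -> pd.DataFrame:
    """Per-subject median of each feature over all qualified beats of all
    recordings; returns a DataFrame indexed by subject with a ``label``
    column and one column per feature id."""
    if not bags:
        raise ValueError("no recording bags supplied")
    frames = []
    for bag in bags:
        df = pd.DataFrame(bag.features, columns=list(FEATURE_IDS))
        df["subject_id"] = bag.subject_id
        df["label"] = bag.label
        frames.append(df)
    allb = pd.concat(frames, ignore_index=True)
    labels = allb.groupby("subject_id")["label"].first()
    med = allb.groupby("subject_id")[list(FEATURE_IDS)].median()
    med.insert(0, "label", labels)
    return med


def _cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """P(x > y) - P(x < y) by full pair comparison."""
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).mean())


def _mwu_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_feature_groups(summary: pd.DataFrame) -> list[FeatureComparison]:
    """Mann-Whitney + Cliff's delta + Bonferroni for every catalog feature.

    ``summary`` is the output of :func:`subject_feature_summary` for the
    combined cohort (``label`` in {healthy, oHCM}).  Requires at least two
    subjects per group.
    """
    healthy = summary[summary["label"] == "healthy"]
    ohcm = summary[summary["label"] == "oHCM"]
    if len(healthy) < 2 or len(ohcm) < 2:
        raise ValueError("need >= 2 subjects per group")
    out = []
    for (fid, name, _group, _unit) in FEATURE_CATALOG:
        h = healthy[fid].to_numpy(dtype=float)
        o = ohcm[fid].to_numpy(dtype=float)
        if np.ptp(np.concatenate([h, o])) == 0:
            p, delta = 1.0, 0.0
        else:
            p = _mwu_pvalue(o, h)
            delta = _cliffs_delta(o, h)
        adj = min(1.0, p * N_FEATURES)
        out.append(FeatureComparison(
            feature_id=fid, name=name, n_healthy=len(h), n_ohcm=len(o),
            median_healthy=float(np.median(h)), median_ohcm=float(np.median(o)),
            effect_size=delta, raw_p=p, adjusted_p=adj,
            significant=adj < ALPHA))
    return out


def volcano_table(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    """Effect magnitude vs -log10 adjusted p, one row per feature, sorted
    by adjusted p (the table behind the usual volcano display)."""
    rows = [{
        "feature_id": c.feature_id,
        "name": c.name,
        "effect_magnitude": abs(c.effect_size),
        "neg_log10_adjusted_p": float(-np.log10(max(c.adjusted_p, 1e-300))),
        "significant": c.significant,
    } for c in comparisons]
    return pd.DataFrame(rows).sort_values(
        "neg_log10_adjusted_p", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def comparisons_frame(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    """Flat CSV-ready frame: feature_id, name, delta, raw_p, adjusted_p,
    significant."""
    return pd.DataFrame([{
        "feature_id": c.feature_id, "name": c.name, "delta": c.effect_size,
        "raw_p": c.raw_p, "adjusted_p": c.adjusted_p,
        "significant": c.significant} for c in comparisons])
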