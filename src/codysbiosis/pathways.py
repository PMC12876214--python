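"""Reporter-score pathway aggregation of per-KO group differences.

Each KEGG Orthology (KO) gene family is tested between groups (Wilcoxon
rank-sum by default, Welch t selectable), the two-sided p-value is mapped
to a signed z-score ``z = Phi^-1(1 - p/2) * sign(case median - control
median)``, and member-KO z-scores are aggregated per pathway as
``z_raw = sum(z) / sqrt(k)``.  Raw pathway scores are then standardised
against a size-matched random background: for each member count k,
``n_background`` random k-subsets of all observed KOs give the null mean
and SD, and ``ReporterScore = (z_raw - mu_k) / sigma_k``.  A pathway is
flagged significant when |ReporterScore| exceeds the threshold (default
1.5).

The signed two-sided conversion makes direction explicit; the classic
one-sided form ``Phi^-1(1 - p)`` is selectable via ``one_sided=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .differential import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

P_FLOOR = 1e-10

UP, DOWN = "up_in_case", "down_in_case"


def ko_group_zscores(ko_table: pd.DataFrame, labels, case: str, control: str,
                     test: str = "wilcoxon") -> pd.Series:
    """Per-KO signed z-scores from two-sided between-group tests.

    ``ko_table`` is samples x KOs; ``labels`` maps sample -> group.  KOs
    absent (all-zero) in every sample are dropped with a log entry.  Each
    group must keep at least 3 samples.  p-values are clamped to
    ``[1e-10, 1 - 1e-10]`` before the normal-quantile transform; a zero
    case-control median difference yields z = 0.
    """
    labels = pd.Series(labels, index=ko_table.index) if not isinstance(
        labels, pd.Series) else labels.loc[ko_table.index]
    for g in (case, control):
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples")
    xi = ko_table.loc[labels == case]
    yi = ko_table.loc[labels == control]
    z = {}
    dropped = []
    for ko in ko_table.columns:
        x, y = xi[ko].values, yi[ko].values
        if np.all(x == 0) and np.all(y == 0):
            dropped.append(ko)
            continue
        if test == "wilcoxon":
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0
            else:
                _, p = wilcoxon_rank_sum(x, y)
        elif test == "t":
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        else:
            raise ValueError(f"unknown test {test!r}")
        p = float(np.clip(p, P_FLOOR, 1.0 - P_FLOOR))
        sign = np.sign(np.median(x) - np.median(y))
        z[ko] = float(stats.norm.ppf(1.0 - p / 2.0) * sign)
    if dropped:
        logger.info("dropped %d all-zero KOs: %s", len(dropped), dropped[:10])
    return pd.Series(z, name="z")


@dataclass
class ReporterResult:
    frame: pd.DataFrame  # per pathway: k, z_raw, z_adjusted, direction, significant
    threshold: float
    n_background: int
    seed: int | None

    def significant_pathways(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]


def pathway_members(pathway_map) -> dict:
    """Normalise a pathway map into {pathway_id: [ko_id, ...]}.

    Accepts a dict already in that shape or a DataFrame with ``pathway_id``
    and ``ko_id`` columns (the TSV layout: pathway_id, level1..3, ko_id).
    """
    if isinstance(pathway_map, dict):
        return {p: list(kos) for p, kos in pathway_map.items()}
    need = {"pathway_id", "ko_id"}
    if not need.issubset(pathway_map.columns):
        raise ValueError("pathway map needs 'pathway_id' and 'ko_id' columns")
    return {p: list(sub["ko_id"]) for p, sub in pathway_map.groupby("pathway_id")}


class ReporterScorer(BaseEstimator):
    """Estimator computing background-corrected reporter scores.

    ``fit(ko_z, pathway_map)`` takes per-KO signed z-scores (from
    :func:`ko_group_zscores`) and a pathway membership map, and exposes
    ``result_`` (:class:`ReporterResult`).  Background sets are drawn with
    replacement across pathways but without replacement within a set; the
    null moments are cached per distinct member count k and are reproducible
    from ``seed``.
    """

    def __init__(self, n_background: int = 1000, threshold: float = 1.5,
                 seed: int | None = None):
        self.n_background = n_background
        self.threshold = threshold
        self.seed = seed

    def fit(self, ko_z: pd.Series, pathway_map) -> "ReporterScorer":
        members = pathway_members(pathway_map)
        zvals = np.asarray(ko_z.values, dtype=float)
        if zvals.size == 0:
            raise ValueError("no KO z-scores supplied")
        observed = set(ko_z.index)

        rows = {}
        ks = set()
        for pw, kos in members.items():
            present = [k for k in kos if k in observed]
            if not present:
                logger.info("pathway %s has no observed member KOs; dropped", pw)
                continue
            k = len(present)
            ks.add(k)
            z_raw = float(ko_z.loc[present].sum() / np.sqrt(k))
            rows[pw] = {"k": k, "z_raw": z_raw}
        if not rows:
            raise ValueError("no pathway has observed member KOs")

        rng = np.random.default_rng(self.seed)
        null_moments = {}
        for k in sorted(ks):
            if k > zvals.size:
                raise ValueError(
                    f"pathway of size {k} exceeds the KO universe ({zvals.size})"
                )
            draws = np.empty(self.n_background)
            for i in range(self.n_background):
                take = rng.choice(zvals.size, size=k, replace=False)
                draws[i] = zvals[take].sum() / np.sqrt(k)
            mu, sd = float(draws.mean()), float(draws.std(ddof=1))
            if sd <= 1e-12 * max(1.0, abs(mu)):
                raise ValueError(
                    "degenerate background (sigma_k = 0); the KO universe is "
                    "too small or constant — supply more KOs"
                )
            null_moments[k] = (mu, sd)

        for pw, rec in rows.items():
            mu, sd = null_moments[rec["k"]]
            za = (rec["z_raw"] - mu) / sd
            rec["z_adjusted"] = za
            rec["direction"] = UP if za >= 0 else DOWN
            rec["significant"] = abs(za) > self.threshold
        frame = pd.DataFrame.from_dict(rows, orient="index").sort_values(
            "z_adjusted", key=lambda s: s.abs(), ascending=False
        )
        frame.index.name = "pathway_id"
        self.null_moments_ = null_moments
        self.result_ = ReporterResult(frame, self.threshold,
                                      self.n_background, self.seed)
        return self


def reporter_scores(ko_z: pd.Series, pathway_map, n_background: int = 1000,
                    threshold: float = 1.5, seed: int | None = None,
                    ) -> ReporterResult:
    """Functional wrapper around :class:`ReporterScorer`."""
    est = ReporterScorer(n_background=n_background, threshold=threshold,
                         seed=seed)
    return est.fit(ko_z, pathway_map).result_
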