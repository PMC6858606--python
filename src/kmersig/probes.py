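"""Probe-level count table normalization, testing and ranking.

Implements a three-step control-based normalization of multiplex digital
counting data (lane scaling on positive controls, negative-control background
subtraction with a floor, housekeeping content normalization), two-sided
Wilcoxon rank-sum testing with fold changes per probe, ranking against a
benchmark probe, and rule-table-driven clinical risk stratification from
Gleason score and TNM stage (PSA deliberately excluded).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProbeTable:
    """Probes x samples values with probe roles and clinical sample labels."""

    values: pd.DataFrame  # probes x samples
    roles: pd.Series  # probe -> target | housekeeping | positive_control | negative_control | benchmark
    sample_meta: pd.DataFrame  # index samples; columns condition, risk, recurrence

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.roles.index):
            raise ValueError("roles must be indexed like the value rows")
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta must be indexed like the value columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("probe values must be non-negative")
        if (self.roles == "benchmark").sum() > 1:
            raise ValueError("at most one benchmark probe")

    def rows(self, role: str) -> pd.DataFrame:
        return self.values.loc[self.roles == role]

    def target_ids(self, include_benchmark: bool = True) -> list[str]:
        keep = {"target", "benchmark"} if include_benchmark else {"target"}
        return list(self.roles.index[self.roles.isin(keep)])

    def to_tsv(self, path: str) -> None:
        df = self.values.copy()
        df.insert(0, "role", self.roles)
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path: str, meta_path: str) -> "ProbeTable":
        df = pd.read_csv(values_path, sep="\t", index_col=0)
        roles = df.pop("role")
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(df, roles, meta.loc[df.columns])


def normalize_probe_table(
    raw: ProbeTable,
    housekeeping_ids: Sequence[str] | None = None,
    background_floor: float = 0.5,
) -> ProbeTable:
    """Three-step control-based normalization.

    1. Lane scaling: per-sample factor = (geometric mean over samples of the
       per-sample positive-control geomeans) / (this sample's geomean).
    2. Background: subtract the per-sample mean of negative controls, floored
       at `background_floor`.
    3. Content: divide by the arithmetic mean of the sample's housekeeping
       values after steps 1-2.
    """
    pos = raw.rows("positive_control")
    neg = raw.rows("negative_control")
    if housekeeping_ids is None:
        housekeeping_ids = list(raw.roles.index[raw.roles == "housekeeping"])
    missing = [h for h in housekeeping_ids if h not in raw.values.index]
    if missing or not housekeeping_ids:
        raise ValueError(f"missing housekeeping rows: {missing or 'none given'}")
    if pos.empty:
        raise ValueError("positive-control rows required for lane scaling")

    with np.errstate(divide="raise"):
        try:
            lane_geo = np.exp(np.log(pos.to_numpy()).mean(axis=0))
        except FloatingPointError as exc:
            raise ValueError("zero positive-control value: lane geomean undefined") from exc
    if np.any(lane_geo <= 0):
        raise ValueError("zero positive-control geomean")
    target_geo = np.exp(np.mean(np.log(lane_geo)))
    lane_factor = target_geo / lane_geo

    scaled = raw.values * lane_factor[None, :]
    background = scaled.loc[neg.index].mean(axis=0) if not neg.empty else 0.0
    adjusted = (scaled - background).clip(lower=background_floor)
    hk_mean = adjusted.loc[list(housekeeping_ids)].mean(axis=0)
    normalized = adjusted / hk_mean
    return ProbeTable(normalized, raw.roles.copy(), raw.sample_meta.copy())


@dataclass
class ProbeTestResult:
    probe_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float


def mwu_asymptotic_p(b: np.ndarray, a: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by a refined normal approximation.

    Continuity-corrected normal with an Edgeworth kurtosis term
    (gamma2 = -(6/5)(m^2+n^2+mn+m+n) / (mn(m+n+1)), exact for tie-free
    data); the plain correction alone leaves mid-range errors of ~0.011 at
    m=n=8, the kurtosis term brings them below 0.001.  With ties, falls back
    to the tie-corrected normal approximation.
    """
    m, n = len(b), len(a)
    pooled = np.concatenate([b, a])
    if len(np.unique(pooled)) < m + n:  # ties: midranks + tie-corrected sigma
        return float(
            stats.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic").pvalue
        )
    u = float(stats.mannwhitneyu(b, a, alternative="two-sided").statistic)
    mu = m * n / 2.0
    var = m * n * (m + n + 1) / 12.0
    sd = np.sqrt(var)
    g2 = -(6.0 / 5.0) * (m * m + n * n + m * n + m + n) / (m * n * (m + n + 1))

    def edge_sf(z: float) -> float:
        return float(stats.norm.sf(z) + stats.norm.pdf(z) * (g2 / 24) * (z**3 - 3 * z))

    z_hi = (u - 0.5 - mu) / sd
    z_lo = (u + 0.5 - mu) / sd
    sf = edge_sf(z_hi)
    cdf = 1.0 - edge_sf(z_lo)
    return float(min(1.0, 2.0 * min(sf, cdf)))


def wilcoxon_fc(
    table: ProbeTable,
    contrast: tuple[str, str] = ("normal", "tumor"),
    label_column: str = "condition",
    pseudocount: float = 0.5,
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test and fold change per probe.

    Exact enumeration when both groups have <= 8 samples and no ties;
    otherwise the tie-corrected normal approximation.  FC is
    mean(group2)/mean(group1), with `pseudocount` added to both means when
    either is zero.
    """
    la, lb = contrast
    meta = table.sample_meta[label_column]
    ga = table.values.columns[meta == la]
    gb = table.values.columns[meta == lb]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"empty group in contrast {contrast}")
    if probes is None:
        probes = table.target_ids()
    rows = []
    for pid in probes:
        a = table.values.loc[pid, ga].to_numpy(dtype=float)
        b = table.values.loc[pid, gb].to_numpy(dtype=float)
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        if len(a) <= 8 and len(b) <= 8 and not ties:
            p = float(
                stats.mannwhitneyu(b, a, alternative="two-sided", method="exact").pvalue
            )
        else:
            p = mwu_asymptotic_p(b, a)
        ma, mb = float(a.mean()), float(b.mean())
        if ma == 0.0 or mb == 0.0:
            fc = (mb + pseudocount) / (ma + pseudocount)
        else:
            fc = mb / ma
        rows.append(
            {"probe_id": pid, "mean_a": ma, "mean_b": mb, "fold_change": fc, "p_value": p}
        )
    return pd.DataFrame(rows).set_index("probe_id")


def rank_and_flag(
    results: pd.DataFrame,
    benchmark_id: str,
    p_cut: float = 0.01,
    fc_cut: float | None = None,
) -> pd.DataFrame:
    """Rank probes by ascending p (ties by descending FC) and flag probes that
    are significant (strict cuts) or ranked better than the benchmark."""
    if benchmark_id not in results.index:
        raise ValueError(f"unknown benchmark {benchmark_id!r}")
    ranked = results.sort_values(
        ["p_value", "fold_change"], ascending=[True, False]
    ).copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    sig = ranked["p_value"] < p_cut
    if fc_cut is not None:
        sig &= ranked["fold_change"] > fc_cut
    ranked["significant"] = sig
    bench_rank = int(ranked.loc[benchmark_id, "rank"])
    ranked["better_than_benchmark"] = ranked["rank"] < bench_rank
    return ranked


# ---------------------------------------------------------------------------
# risk stratification

_STAGE_ORDER = ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4"]
_STAGE_RANK = {s: i for i, s in enumerate(_STAGE_ORDER)}


def _stage_rank(stage: str) -> int | None:
    if not isinstance(stage, str):
        return None
    m = re.match(r"^T(\d)([abc]?)", stage.strip(), flags=re.IGNORECASE)
    if not m:
        return None
    key = f"T{m.group(1)}{m.group(2).lower()}"
    if key in _STAGE_RANK:
        return _STAGE_RANK[key]
    # bare T2/T3: place at the first sub-stage
    key = f"T{m.group(1)}a"
    return _STAGE_RANK.get(key)


def load_default_risk_rules() -> pd.DataFrame:
    """Rule table shipped as data: first-match rows with inclusive bounds on
    Gleason score and TNM stage (PSA-free risk grouping)."""
    with resources.files("kmersig").joinpath("data/risk_rules.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def stratify_risk(
    metadata: pd.DataFrame,
    rule_table: pd.DataFrame | None = None,
    gleason_column: str = "gleason",
    stage_column: str = "t_stage",
) -> pd.Series:
    """Assign LR / IR / HR labels by the first matching rule.

    The rule table has columns label, gleason_min, gleason_max, stage_min,
    stage_max; '*' means unbounded.  Missing or unparseable fields give NA.
    """
    if rule_table is None:
        rule_table = load_default_risk_rules()

    def bound(v, default):
        return default if (pd.isna(v) or v == "*") else v

    labels = {}
    for sid, row in metadata.iterrows():
        g = row.get(gleason_column)
        st = row.get(stage_column)
        if pd.isna(g) or pd.isna(st):
            labels[sid] = "NA"
            continue
        srank = _stage_rank(str(st))
        if srank is None:
            warnings.warn(f"unparseable stage {st!r} for sample {sid}")
            labels[sid] = "NA"
            continue
        g = float(g)
        label = "NA"
        for _, rule in rule_table.iterrows():
            gmin = float(bound(rule["gleason_min"], -np.inf))
            gmax = float(bound(rule["gleason_max"], np.inf))
            smin = _stage_rank(str(bound(rule["stage_min"], "T1a")))
            smax = _stage_rank(str(bound(rule["stage_max"], "T4")))
            if gmin <= g <= gmax and smin <= srank <= smax:
                label = rule["label"]
                break
        labels[sid] = label
    return pd.Series(labels, name="risk")
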