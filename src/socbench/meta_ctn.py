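"""Meta-analysis of close-to-nature plantation management effects on SOC.

Effect size per study is the natural-log response ratio
``RR = ln(xt / xc)`` with sampling variance
``v = St^2/(nt xt^2) + Sc^2/(nc xc^2)``; a missing SD is imputed as one
tenth of its mean (and flagged). Pooling uses the DerSimonian-Laird
random-effects estimator with normal-quantile (1.96) confidence limits;
the pooled effect back-transforms to a percent change ``(e^RR - 1) x 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["study_id", "xt", "xc", "st", "sc", "nt", "nc", "duration", "depth"]


@dataclass
class MetaRecord:
    """One study's treatment/control summary (same SOC units both arms)."""

    study_id: str
    xt: float
    xc: float
    st: float | None
    sc: float | None
    nt: int
    nc: int
    duration: float | None = None
    depth: float | None = None

    def validate(self) -> "MetaRecord":
        if not (self.xt > 0 and self.xc > 0):
            raise ValueError(f"{self.study_id}: treatment/control means must be > 0")
        if self.nt < 1 or self.nc < 1:
            raise ValueError(f"{self.study_id}: replicate counts must be >= 1")
        for s in (self.st, self.sc):
            if s is not None and not np.isnan(s) and s < 0:
                raise ValueError(f"{self.study_id}: SDs must be >= 0")
        return self


@dataclass
class MetaResult:
    pooled_rr: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    df: int
    k: int
    n_imputed: int

    @property
    def percent_change(self) -> float:
        return (np.exp(self.pooled_rr) - 1.0) * 100.0

    @property
    def percent_ci(self) -> tuple[float, float]:
        return ((np.exp(self.ci_low) - 1.0) * 100.0,
                (np.exp(self.ci_high) - 1.0) * 100.0)


def effect_size(rec: MetaRecord) -> tuple[float, float, bool]:
    """ln response ratio, its sampling variance, and an imputation flag."""
    rec.validate()
    st, sc = rec.st, rec.sc
    imputed = False
    if st is None or np.isnan(st):
        st, imputed = rec.xt / 10.0, True
    if sc is None or np.isnan(sc):
        sc, imputed = rec.xc / 10.0, True
    rr = np.log(rec.xt) - np.log(rec.xc)
    v = st**2 / (rec.nt * rec.xt**2) + sc**2 / (rec.nc * rec.xc**2)
    return float(rr), float(v), imputed


def _records_from_frame(df: pd.DataFrame) -> list[MetaRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(MetaRecord(
            study_id=str(row["study_id"]), xt=float(row["xt"]), xc=float(row["xc"]),
            st=float(row["st"]) if pd.notna(row.get("st")) else None,
            sc=float(row["sc"]) if pd.notna(row.get("sc")) else None,
            nt=int(row["nt"]), nc=int(row["nc"]),
            duration=float(row["duration"]) if pd.notna(row.get("duration")) else None,
            depth=float(row["depth"]) if pd.notna(row.get("depth")) else None,
        ))
    return recs


def pool_random_effects(records) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of ln response ratios.

    tau^2 = max(0, (Q - (k-1)) / C) with C = sum(w) - sum(w^2)/sum(w) under
    fixed weights w = 1/v; final weights are 1/(v + tau^2). With all v equal
    and tau^2 = 0 this reduces exactly to the arithmetic mean of study RRs.
    """
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)
    k = len(records)
    if k < 2:
        raise ValueError(f"random-effects pooling needs k >= 2 studies, got {k}")
    out = [effect_size(r) for r in records]
    rr = np.array([o[0] for o in out])
    v = np.array([o[1] for o in out])
    n_imputed = sum(o[2] for o in out)

    with np.errstate(divide="ignore"):
        w = 1.0 / v
    if np.isinf(w).any():
        # zero-variance studies dominate exactly; cap at a huge finite weight
        w = np.where(np.isinf(w), 1e12, w)
    mean_fixed = float(np.sum(w * rr) / np.sum(w))
    q = float(np.sum(w * (rr - mean_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0

    w_star = 1.0 / (v + tau2) if tau2 > 0 else w
    pooled = float(np.sum(w_star * rr) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    return MetaResult(pooled_rr=pooled, se=se,
                      ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se,
                      tau2=float(tau2), q=q, df=k - 1, k=k, n_imputed=n_imputed)


@dataclass
class SubgroupResult:
    breaks: list[float]
    results: dict = field(default_factory=dict)   # label -> MetaResult | None
    insufficient: list[str] = field(default_factory=list)


def subgroup_by_duration(records, breaks: list[float] | None = None) -> SubgroupResult:
    """Independent random-effects pooling per management-duration stratum.

    ``breaks`` are year thresholds (default [15]); strata are
    ``<= b1``, ``(b1, b2]``, ..., ``> bn``. Strata with fewer than two
    studies are flagged as insufficient rather than pooled.
    """
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)
    breaks = sorted(breaks) if breaks else []
    for r in records:
        if r.duration is None:
            raise ValueError(f"{r.study_id}: duration required for subgrouping")

    edges = [-np.inf] + list(breaks) + [np.inf]
    out = SubgroupResult(breaks=list(breaks))
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo) and np.isinf(hi):
            label = "all"
        elif np.isinf(lo):
            label = f"<={hi:g}y"
        elif np.isinf(hi):
            label = f">{lo:g}y"
        else:
            label = f"({lo:g},{hi:g}]y"
        members = [r for r in records if lo < r.duration <= hi]
        if len(members) < 2:
            out.results[label] = None
            out.insufficient.append(label)
        else:
            out.results[label] = pool_random_effects(members)
    return out


def read_meta_table(path) -> list[MetaRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ("study_id", "xt", "xc", "nt", "nc") if c not in df.columns]
    if missing:
        raise ValueError(f"meta table missing column(s): {missing}")
    for c in META_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return _records_from_frame(df)
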