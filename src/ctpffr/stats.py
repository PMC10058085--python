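"""Diagnostic-performance evaluation of CTP-FFR against invasive FFR.

Positivity is defined as FFR <= 0.80 for both the index and the reference
test (the boundary value itself is positive; 0.75-0.80 is additionally
flagged as the diagnostic gray zone).  The module provides the 2x2
confusion metrics with exact Clopper-Pearson 95% intervals, ROC/AUC with
the paired DeLong comparison, McNemar and chi-square subgroup tests,
Pearson correlation with a Fisher-z interval, Bland-Altman agreement, and
the stratified analyses (QCA severity, calcium burden, vessel, lesion
location, FFR band).  All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FFR_POSITIVE_THRESHOLD = 0.80
GRAY_ZONE = (0.75, 0.80)
CAC_CUTOFF = 400.0

QCA_STRATA = (("30-49%", 30.0, 50.0), ("50-69%", 50.0, 70.0),
              ("≥70%", 70.0, np.inf))
FFR_BANDS = (("≤0.70", -np.inf, 0.70), ("0.70-0.80", 0.70, 0.80),
             ("0.80-0.90", 0.80, 0.90), (">0.90", 0.90, np.inf))


@dataclass
class VesselRecord:
    vessel_id: str
    patient_id: str
    ctp_ffr: float
    invasive_ffr: float
    qca_percent: float
    cac_class: str  # "<400" | ">=400"
    vessel_name: str  # LAD | LCX
    lesion_location: str  # proximal | middle | distal

    def __post_init__(self) -> None:
        for name in ("ctp_ffr", "invasive_ffr"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def gray_zone(self) -> bool:
        return GRAY_ZONE[0] <= self.invasive_ffr <= GRAY_ZONE[1]


def records_from_dataframe(df: pd.DataFrame) -> list[VesselRecord]:
    cols = ["vessel_id", "patient_id", "ctp_ffr", "invasive_ffr",
            "qca_percent", "cac_class", "vessel_name", "lesion_location"]
    return [VesselRecord(**{c: row[c] for c in cols}) for _, row in df.iterrows()]


def records_from_band_counts(band_counts: dict[str, tuple[int, int]]
                             ) -> list[VesselRecord]:
    """Reconstruct per-vessel records from per-FFR-band (total, correct) counts.

    Each band contributes ``total`` vessels with a representative invasive
    FFR at the band midpoint; ``correct`` of them get a concordant CTP-FFR
    and the rest a discordant one.  This is the desk-scale route from
    published stratum counts back to a 2x2 table via ``classify``.
    """
    reps = {"≤0.70": 0.60, "0.70-0.80": 0.75, "0.80-0.90": 0.85,
            ">0.90": 0.95}
    recs = []
    i = 0
    for band, (total, correct) in band_counts.items():
        ref = reps[band]
        truth_pos = ref <= FFR_POSITIVE_THRESHOLD
        for j in range(total):
            agree = j < correct
            pos = truth_pos if agree else not truth_pos
            ctp = 0.70 if pos else 0.90
            recs.append(VesselRecord(f"V{i:03d}", f"P{i:03d}", ctp, ref,
                                     60.0, "<400", "LAD", "proximal"))
            i += 1
    return recs


# ---------------------------------------------------------------------------
# confusion table and metrics

@dataclass
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.tp + other.tp, self.fp + other.fp,
                              self.tn + other.tn, self.fn + other.fn)


def classify(records: Sequence[VesselRecord],
             index_threshold: float = FFR_POSITIVE_THRESHOLD,
             reference_threshold: float = FFR_POSITIVE_THRESHOLD,
             ) -> ConfusionTable:
    """2x2 table of index (CTP-FFR) against reference (invasive FFR).

    A vessel is positive when its value is <= the threshold; the boundary
    counts as positive.
    """
    if len(records) == 0:
        raise ValueError("no records to classify")
    tp = fp = tn = fn = 0
    for r in records:
        pred = r.ctp_ffr <= index_threshold
        truth = r.invasive_ffr <= reference_threshold
        if pred and truth:
            tp += 1
        elif pred:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, tn, fn)


class Proportion(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Proportion:
    """Exact binomial (Clopper-Pearson) two-sided interval for k successes of n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.isf(alpha / 2, k + 1, n - k))
    return Proportion(k / n, lo, hi)


@dataclass
class MetricSet:
    sensitivity: Proportion | None
    specificity: Proportion | None
    accuracy: Proportion | None
    ppv: Proportion | None
    npv: Proportion | None

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            p = getattr(self, name)
            out[name] = None if p is None else {
                "estimate": p.estimate, "ci": [p.ci_low, p.ci_high]}
        return out


def confusion_metrics(table: ConfusionTable, ci_method: str = "clopper-pearson",
                      ) -> MetricSet:
    """Sensitivity, specificity, accuracy, PPV, NPV with exact 95% CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    if ci_method != "clopper-pearson":
        raise ValueError(f"unsupported CI method {ci_method!r}")
    if table.total == 0:
        raise ValueError("empty confusion table")

    def prop(k: int, n: int) -> Proportion | None:
        return clopper_pearson(k, n) if n > 0 else None

    return MetricSet(
        sensitivity=prop(table.tp, table.tp + table.fn),
        specificity=prop(table.tn, table.tn + table.fp),
        accuracy=prop(table.tp + table.tn, table.total),
        ppv=prop(table.tp, table.tp + table.fp),
        npv=prop(table.tn, table.tn + table.fn),
    )


# ---------------------------------------------------------------------------
# ROC / AUC, DeLong

def _structural_components(scores: np.ndarray, labels: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its positive/negative placement (structural) components,
    with midranks giving half credit to ties."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    r_all = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (r_all[:m] - r_pos) / n  # per-positive placement values
    v_neg = 1.0 - (r_all[m:] - r_neg) / m  # per-negative placement values
    return float(auc), v_pos, v_neg


def roc_auc(scores, labels, positive_lower: bool = True
            ) -> tuple[float, float]:
    """AUC (Mann-Whitney with tie credit) and its DeLong variance.

    ``labels`` are reference positives; ``positive_lower`` states the score
    orientation (a lower CTP-FFR is more diseased).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    s = -scores if positive_lower else scores
    auc, v_pos, v_neg = _structural_components(s, labels)
    m, n = v_pos.size, v_neg.size
    var = (np.var(v_pos, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v_neg, ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


class DegenerateTestError(ValueError):
    """Comparison is degenerate (zero variance with unequal estimates)."""


def delong_test(scores_a, scores_b, labels, positive_lower: bool = True
                ) -> tuple[float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same records.

    Returns (z, two-sided p) from the structural-component covariance.
    Identical estimates with zero variance (e.g. the same scores twice)
    give (0, 1); unequal estimates with zero variance raise.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise ValueError("paired scores and labels must be congruent")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if positive_lower:
        sa, sb = -sa, -sb
    auc_a, va_pos, va_neg = _structural_components(sa, labels)
    auc_b, vb_pos, vb_neg = _structural_components(sb, labels)
    m, n = va_pos.size, va_neg.size
    s_pos = np.cov(np.vstack([va_pos, vb_pos])) if m > 1 else np.zeros((2, 2))
    s_neg = np.cov(np.vstack([va_neg, vb_neg])) if n > 1 else np.zeros((2, 2))
    s = s_pos / m + s_neg / n
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0.0:
            return 0.0, 1.0
        raise DegenerateTestError("zero variance with unequal AUCs")
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# paired / correlation / agreement tests

def mcnemar_test(discordant_b: int, discordant_c: int,
                 exact_threshold: int = 25) -> float:
    """Two-sided McNemar p for discordant-pair counts.

    Exact binomial when b + c < ``exact_threshold``; chi-square with
    continuity correction otherwise.  b = c = 0 returns 1 by convention.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_threshold:
        return float(sps.binomtest(b, n, 0.5).pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return float(sps.chi2.sf(chi2, df=1))


def chi_square_accuracy(correct_by_stratum: dict[str, tuple[int, int]]
                        ) -> tuple[float, float]:
    """Chi-square comparison of accuracies across strata.

    ``correct_by_stratum`` maps stratum -> (correct, total).  Falls back to
    Fisher's exact test for 2x2 layouts with small expected counts.
    """
    names = list(correct_by_stratum)
    table = np.array([[correct_by_stratum[k][0],
                       correct_by_stratum[k][1] - correct_by_stratum[k][0]]
                      for k in names])
    if table.shape[0] == 2 and (sps.contingency.expected_freq(table) < 5).any():
        res = sps.fisher_exact(table)
        return float("nan"), float(res.pvalue)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def pearson_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r = float(sps.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1.0 + 1e-16, 1.0 - 1e-16))
    half = sps.norm.isf(alpha / 2) / np.sqrt(x.size - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +- 1.96 SD, ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired values")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


# ---------------------------------------------------------------------------
# stratification

def _stratum_of(record: VesselRecord, scheme: str) -> str:
    if scheme == "qca":
        for name, lo, hi in QCA_STRATA:
            if lo <= record.qca_percent < hi:
                return name
        raise ValueError(f"QCA {record.qca_percent} outside strata")
    if scheme == "cac":
        return record.cac_class
    if scheme == "vessel_name":
        return record.vessel_name
    if scheme == "lesion_location":
        return record.lesion_location
    if scheme == "ffr_band":
        for name, lo, hi in FFR_BANDS:
            if lo < record.invasive_ffr <= hi:
                return name
        raise ValueError(f"FFR {record.invasive_ffr} outside bands")
    raise ValueError(f"unknown stratification scheme {scheme!r}")


def stratify(records: Sequence[VesselRecord], scheme: str
             ) -> dict[str, tuple[ConfusionTable, MetricSet]]:
    """Exhaustive disjoint partition of records with per-stratum metrics."""
    groups: dict[str, list[VesselRecord]] = {}
    for r in records:
        groups.setdefault(_stratum_of(r, scheme), []).append(r)
    return {k: (t := classify(v), confusion_metrics(t))
            for k, v in sorted(groups.items())}


def per_patient_records(records: Sequence[VesselRecord]) -> list[VesselRecord]:
    """Worst-vessel aggregation: one record per patient carrying the minimum
    CTP-FFR and minimum invasive FFR over that patient's vessels."""
    by_pat: dict[str, list[VesselRecord]] = {}
    for r in records:
        by_pat.setdefault(r.patient_id, []).append(r)
    out = []
    for pid, rs in sorted(by_pat.items()):
        worst = min(rs, key=lambda r: r.invasive_ffr)
        out.append(VesselRecord(
            vessel_id=pid, patient_id=pid,
            ctp_ffr=min(r.ctp_ffr for r in rs),
            invasive_ffr=min(r.invasive_ffr for r in rs),
            qca_percent=worst.qca_percent, cac_class=worst.cac_class,
            vessel_name=worst.vessel_name, lesion_location=worst.lesion_location))
    return out


def combine_tests(predictions: Sequence[np.ndarray], rule: str = "or") -> np.ndarray:
    """Logical combiner for multiple index tests (positivity vectors)."""
    preds = np.vstack([np.asarray(p, dtype=bool) for p in predictions])
    if rule == "or":
        return preds.any(axis=0)
    if rule == "and":
        return preds.all(axis=0)
    raise ValueError(f"unknown combination rule {rule!r}")


# ---------------------------------------------------------------------------
# null-calibration Monte Carlo

def delong_type_i_error(n: int = 60, reps: int = 500, seed: int = 0,
                        alpha: float = 0.05) -> float:
    """Empirical size of the paired DeLong test under a permuted-label null.

    Each replicate draws two equally informative, correlated score vectors
    (shared latent severity plus independent noise) and permutes the
    reference labels, breaking any label-score association while keeping
    the pairing; the rejection rate at ``alpha`` estimates the type-I
    error.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < reps:
        latent = rng.standard_normal(n)
        sa = latent + rng.standard_normal(n)
        sb = latent + rng.standard_normal(n)
        y = rng.permutation(latent + rng.standard_normal(n) > 0)
        if y.all() or not y.any():
            continue
        done += 1
        try:
            _, p = delong_test(sa, sb, y)
        except DegenerateTestError:  # pragma: no cover
            continue
        if p < alpha:
            hits += 1
    return hits / reps


def mcnemar_type_i_error(n: int = 60, reps: int = 500, seed: int = 0,
                         alpha: float = 0.05, error_rate: float = 0.13,
                         prevalence: float = 0.46) -> float:
    """Empirical size of the McNemar rule under an exchangeable paired null.

    Each replicate draws a reference truth and two diagnostic reads with
    the same ``error_rate`` (matching the observed diagnostic accuracy),
    then randomly exchanges the two reads within each pair -- the paired
    label permutation under which both tests have identical accuracy by
    construction.  The exact-binomial branch is discrete and therefore
    conservative at small discordance counts.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        truth = rng.random(n) < prevalence
        pa = truth ^ (rng.random(n) < error_rate)
        pb = truth ^ (rng.random(n) < error_rate)
        swap = rng.random(n) < 0.5
        pa2 = np.where(swap, pb, pa)
        pb2 = np.where(swap, pa, pb)
        b = int(((pa2 == truth) & (pb2 != truth)).sum())
        c = int(((pa2 != truth) & (pb2 == truth)).sum())
        if mcnemar_test(b, c) < alpha:
            hits += 1
    return hits / reps


# ---------------------------------------------------------------------------
# full evaluation report

def evaluate_records(records: Sequence[VesselRecord]) -> dict:
    """Complete per-vessel evaluation: confusion metrics, AUC, correlation,
    agreement, and all stratified tables, as a JSON-ready dict."""
    records = list(records)
    table = classify(records)
    metrics = confusion_metrics(table)
    ctp = np.array([r.ctp_ffr for r in records])
    inv = np.array([r.invasive_ffr for r in records])
    labels = inv <= FFR_POSITIVE_THRESHOLD

    report: dict = {
        "n_vessels": len(records),
        "n_patients": len({r.patient_id for r in records}),
        "prevalence": float(labels.mean()),
        "confusion": {"tp": table.tp, "fp": table.fp,
                      "tn": table.tn, "fn": table.fn},
        "metrics": metrics.as_dict(),
        "gray_zone_n": sum(r.gray_zone for r in records),
    }
    if labels.any() and not labels.all():
        auc, var = roc_auc(ctp, labels)
        report["auc"] = {"estimate": auc, "delong_se": float(np.sqrt(var))}
    try:
        r, ci = pearson_with_ci(ctp, inv)
        report["pearson"] = {"r": r, "ci": list(ci)}
    except ValueError:
        report["pearson"] = None
    try:
        mean, lo, hi = bland_altman(ctp, inv)
        report["bland_altman"] = {"mean_difference": mean, "loa": [lo, hi]}
    except ValueError:
        report["bland_altman"] = None
    report["strata"] = {
        scheme: {
            name: {"confusion": {"tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn},
                   "metrics": m.as_dict()}
            for name, (t, m) in stratify(records, scheme).items()
        }
        for scheme in ("qca", "cac", "vessel_name", "lesion_location", "ffr_band")
    }
    return report
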