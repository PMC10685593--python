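"""Agreement and error statistics for method-comparison of Cobb measurements.

Covers the evaluation battery used to validate automatic against reference
measurements: PCK (percentage of correct key points) against per-landmark
distance fences, the matched-samples t test, the intraclass correlation
coefficient with its conventional interpretation bands, Pearson correlation
with a Fisher-z confidence interval, mean absolute error with a bootstrap
interval, and Bland–Altman limits of agreement.

ICC form: two-way random effects, absolute agreement, single measures
(ICC(2,1)) — the standard choice for method comparison, since absolute
agreement penalizes systematic bias in the same spirit as Bland–Altman.
Computation is delegated to :func:`pingouin.intraclass_corr`, with the
degenerate exact-equality case (zero residual mean square) handled
explicitly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import OutlierFence, pairwise_distance
from .volume_io import LANDMARK_NAMES, LandmarkSet, ValidationError

__all__ = [
    "ICCResult",
    "PearsonResult",
    "MAEResult",
    "PairedTResult",
    "BlandAltmanResult",
    "AgreementReport",
    "pck",
    "paired_t_test",
    "icc_two_way",
    "pearson",
    "mae",
    "bland_altman",
    "build_report",
]

#: Bootstrap resamples for the MAE confidence interval.
MAE_BOOTSTRAP_N = 2000
#: Normal quantile used for the Bland–Altman limits of agreement.
LOA_MULTIPLIER = 1.96


def _icc_band(icc: float) -> str:
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "general"
    if icc < 0.75:
        return "good"
    return "excellent"


def _r_band(r: float) -> str:
    a = abs(r)
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    if a < 0.8:
        return "strong"
    return "extremely strong"


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci95: tuple[float, float]
    band: str


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci95: tuple[float, float]
    band: str


@dataclass(frozen=True)
class MAEResult:
    value: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    significant: bool | None  # None when t is undefined
    note: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]


def _paired(x, y, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired lists must be 1-D and of equal length")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pck(
    pred: list[LandmarkSet], ref: list[LandmarkSet], fence: OutlierFence
) -> dict[str, float]:
    """Per-landmark fraction of predictions strictly within the distance fence.

    A predicted key point counts as correct iff its distance to the reference
    point is strictly less than that landmark's Tp; a distance exactly equal
    to Tp is incorrect.
    """
    if len(pred) != len(ref):
        raise ValidationError("pred and ref landmark lists differ in length")
    for p, r in zip(pred, ref):
        if p.case_id != r.case_id:
            raise ValidationError(f"case mismatch: {p.case_id} vs {r.case_id}")
    out = {}
    for name in LANDMARK_NAMES:
        tp = fence.tp(name)
        hits = sum(pairwise_distance(p, r, name) < tp for p, r in zip(pred, ref))
        out[name] = hits / len(pred)
    return out


def paired_t_test(x, y) -> PairedTResult:
    """Matched-samples t test on paired measurements.

    ``p > 0.05`` is interpreted as "no significant difference".  Identical
    lists give t = 0, p = 1; constant nonzero differences leave t undefined
    (zero variance) and are flagged.
    """
    x, y = _paired(x, y, min_n=2)
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return PairedTResult(t=0.0, p=1.0, significant=False)
        return PairedTResult(
            t=float("nan"), p=float("nan"), significant=None,
            note="zero-variance differences: t undefined",
        )
    res = stats.ttest_rel(x, y)
    return PairedTResult(
        t=float(res.statistic), p=float(res.pvalue), significant=bool(res.pvalue <= 0.05)
    )


def icc_two_way(x, y) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Interpretation bands: < 0.4 poor, 0.4–0.6 general, 0.6–0.75 good,
    >= 0.75 excellent consistency.
    """
    x, y = _paired(x, y, min_n=3)
    if np.array_equal(x, y):
        if np.all(x == x[0]):
            raise ValidationError("ICC undefined for constant identical ratings")
        return ICCResult(value=1.0, ci95=(1.0, 1.0), band=_icc_band(1.0))
    import pingouin as pg  # deferred: heavy import

    n = x.size
    df = pd.DataFrame(
        {
            "case": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": np.concatenate([x, y]),
        }
    )
    res = pg.intraclass_corr(data=df, targets="case", raters="rater", ratings="score")
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return ICCResult(value=icc, ci95=(lo, min(hi, 1.0)), band=_icc_band(icc))


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with a Fisher-z 95% CI and interpretation band.

    Bands: |r| < 0.4 weak, 0.4–0.6 moderate, 0.6–0.8 strong,
    >= 0.8 extremely strong.
    """
    x, y = _paired(x, y, min_n=3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Pearson r undefined for constant input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) == 1.0:
        ci = (r, r)
    else:
        ci_obj = res.confidence_interval(confidence_level=0.95)
        ci = (float(ci_obj.low), float(ci_obj.high))
    return PearsonResult(r=r, ci95=ci, band=_r_band(r))


def mae(observed, predicted, seed: int = 0, n_boot: int = MAE_BOOTSTRAP_N) -> MAEResult:
    """Mean absolute error with a seeded percentile-bootstrap 95% CI."""
    x, y = _paired(observed, predicted, min_n=1)
    err = np.abs(x - y)
    value = float(err.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, err.size, size=(n_boot, err.size))
    boot = err[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MAEResult(value=value, ci95=(float(lo), float(hi)))


def bland_altman(x, y) -> BlandAltmanResult:
    """Mean difference, SD of differences (n−1), and 95% limits of agreement."""
    x, y = _paired(x, y, min_n=2)
    d = x - y
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=m, sd_diff=sd, loa=(m - LOA_MULTIPLIER * sd, m + LOA_MULTIPLIER * sd)
    )


@dataclass
class AgreementReport:
    """Aggregated agreement metrics for one method-vs-reference comparison."""

    pck_per_landmark: dict[str, float]
    icc: ICCResult
    pearson_r: PearsonResult
    mae_deg: MAEResult
    paired_t: PairedTResult
    bland_altman: BlandAltmanResult

    def __post_init__(self) -> None:
        for name, f in self.pck_per_landmark.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"PCK for {name} outside [0, 1]")
        if self.icc.value > 1.0:
            raise ValidationError("ICC cannot exceed 1")
        if abs(self.pearson_r.r) > 1.0:
            raise ValidationError("|r| cannot exceed 1")
        if self.mae_deg.value < 0:
            raise ValidationError("MAE cannot be negative")
        ba = self.bland_altman
        if not ba.loa[0] <= ba.mean_diff <= ba.loa[1]:
            raise ValidationError("LoA must bracket the mean difference")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AgreementReport":
        doc = json.loads(Path(path).read_text())
        return cls(
            pck_per_landmark=doc["pck_per_landmark"],
            icc=ICCResult(doc["icc"]["value"], tuple(doc["icc"]["ci95"]), doc["icc"]["band"]),
            pearson_r=PearsonResult(
                doc["pearson_r"]["r"], tuple(doc["pearson_r"]["ci95"]), doc["pearson_r"]["band"]
            ),
            mae_deg=MAEResult(doc["mae_deg"]["value"], tuple(doc["mae_deg"]["ci95"])),
            paired_t=PairedTResult(
                doc["paired_t"]["t"],
                doc["paired_t"]["p"],
                doc["paired_t"]["significant"],
                doc["paired_t"]["note"],
            ),
            bland_altman=BlandAltmanResult(
                doc["bland_altman"]["mean_diff"],
                doc["bland_altman"]["sd_diff"],
                tuple(doc["bland_altman"]["loa"]),
            ),
        )

    def to_csv(self, path: str | Path) -> Path:
        """Flatten the report to a two-column (metric, value) CSV."""
        rows = [("pck_" + k, v) for k, v in self.pck_per_landmark.items()]
        rows += [
            ("icc", self.icc.value),
            ("icc_ci_low", self.icc.ci95[0]),
            ("icc_ci_high", self.icc.ci95[1]),
            ("icc_band", self.icc.band),
            ("pearson_r", self.pearson_r.r),
            ("pearson_ci_low", self.pearson_r.ci95[0]),
            ("pearson_ci_high", self.pearson_r.ci95[1]),
            ("pearson_band", self.pearson_r.band),
            ("mae_deg", self.mae_deg.value),
            ("mae_ci_low", self.mae_deg.ci95[0]),
            ("mae_ci_high", self.mae_deg.ci95[1]),
            ("t_statistic", self.paired_t.t),
            ("p_value", self.paired_t.p),
            ("mean_diff", self.bland_altman.mean_diff),
            ("sd_diff", self.bland_altman.sd_diff),
            ("loa_lower", self.bland_altman.loa[0]),
            ("loa_upper", self.bland_altman.loa[1]),
        ]
        path = Path(path)
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, index=False)
        return path


def ba_plot_table(x, y, case_ids=None) -> pd.DataFrame:
    """Per-case (mean, difference) table backing a Bland–Altman plot."""
    x, y = _paired(x, y, min_n=1)
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(x.size)]
    return pd.DataFrame(
        {"case_id": list(case_ids), "mean": 0.5 * (x + y), "difference": x - y}
    )


def build_report(
    pred_landmarks: list[LandmarkSet] | None,
    ref_landmarks: list[LandmarkSet] | None,
    pred_angles,
    ref_angles,
    fence: OutlierFence,
    seed: int = 0,
) -> tuple[AgreementReport, pd.DataFrame]:
    """Assemble the full agreement report plus the Bland–Altman plot table.

    Angle-based metrics compare ``pred_angles`` against ``ref_angles``
    (differences taken as pred − ref); landmark-based PCK uses the fence.
    PCK is empty when either landmark list is absent.
    """
    have_lm = pred_landmarks is not None and ref_landmarks is not None
    report = AgreementReport(
        pck_per_landmark=pck(pred_landmarks, ref_landmarks, fence) if have_lm else {},
        icc=icc_two_way(pred_angles, ref_angles),
        pearson_r=pearson(pred_angles, ref_angles),
        mae_deg=mae(ref_angles, pred_angles, seed=seed),
        paired_t=paired_t_test(pred_angles, ref_angles),
        bland_altman=bland_altman(pred_angles, ref_angles),
    )
    case_ids = [s.case_id for s in pred_landmarks] if have_lm else None
    return report, ba_plot_table(pred_angles, ref_angles, case_ids)
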