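"""Per-trial impairment metrics and study-level statistics.

The primary per-trial outcomes are ranges of motion over the object
displacement phase [t_grasp, t_release): trunk compensation (the Euclidean
norm of the three trunk-angle ranges), elbow and wrist flexion-extension
range, finger flexion-extension (mean of index and middle ranges) and
movement time.  Study-level operations aggregate trials over the task
factors (tested arm, block weight, target height), summarise the clinical
subject table, and relate metrics by Spearman rank correlation with exact
permutation p-values at small n.

The bundled ``data/subjects.csv`` transcribes the published demographic and
clinical table of the ten-subject cohort (one subject was later discarded
from the kinematic analysis; the published territory means include all ten
rows, which the summary reproduces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_io import TrialCondition
from .kinematics import JointAngleSeries
from .segmentation import PhaseDurations, PhaseEvents

ROM_DOFS = (
    "trunk_flexion",
    "trunk_lateral",
    "trunk_torsion",
    "shoulder_flexext",
    "shoulder_abdadd",
    "elbow_flexext",
    "forearm_prosup",
    "wrist_flexext",
    "thumb_flexext",
    "index_flexext",
    "middle_flexext",
)

METRIC_COLUMNS = ("trunk_comp", "elbow_rom", "wrist_rom", "finger_rom")


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined for zero-variance input."""


# ---------------------------------------------------------------------------
# Per-trial metrics
# ---------------------------------------------------------------------------

def range_of_motion(t: np.ndarray, series: np.ndarray, window: tuple[float, float]) -> float:
    """Max minus min of an angle series over the half-open window, degrees."""
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    m = (t >= window[0]) & (t < window[1])
    if not m.any():
        raise ValueError(f"empty range-of-motion window {window}")
    return float(series[m].max() - series[m].min())


def trunk_compensation(range_flexion: float, range_lateral: float, range_torsion: float) -> float:
    """Euclidean norm of the three trunk-angle ranges, degrees."""
    if min(range_flexion, range_lateral, range_torsion) < 0:
        raise ValueError("trunk ranges must be non-negative")
    return math.sqrt(range_flexion**2 + range_lateral**2 + range_torsion**2)


def finger_flexext_metric(index_rom: float, middle_rom: float) -> float:
    """Mean of the index and middle finger flexion-extension ranges."""
    if min(index_rom, middle_rom) < 0:
        raise ValueError("finger ranges must be non-negative")
    return 0.5 * (index_rom + middle_rom)


@dataclass
class TrialMetrics:
    condition: TrialCondition
    rom: dict[str, float]
    trunk_comp: float
    elbow_rom: float
    wrist_rom: float
    finger_rom: float
    movement_time: float
    durations: PhaseDurations
    subject: str = "S01"
    method: str = "manual"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rom.values()):
            raise ValueError("ranges of motion cannot be negative")
        if self.trunk_comp + 1e-9 < max(
            self.rom.get(k, 0.0) for k in ("trunk_flexion", "trunk_lateral", "trunk_torsion")
        ):
            raise ValueError("trunk compensation below one of its component ranges")

    def to_row(self) -> dict:
        c = self.condition
        return {
            "subject": self.subject,
            "arm": c.arm,
            "block": c.block,
            "target": c.target,
            "height": c.height,
            "repetition": c.repetition,
            "trunk_comp": self.trunk_comp,
            "elbow_rom": self.elbow_rom,
            "wrist_rom": self.wrist_rom,
            "finger_rom": self.finger_rom,
            "movement_time": self.movement_time,
            "reach_s": self.durations.reach,
            "displacement_s": self.durations.displacement,
            "return_s": self.durations.return_,
            "method": self.method,
            **{f"rom_{k}": v for k, v in self.rom.items()},
        }


def compute_trial_metrics(
    angles: JointAngleSeries,
    events: PhaseEvents,
    condition: TrialCondition,
    durations: PhaseDurations | None = None,
    subject: str = "S01",
) -> TrialMetrics:
    """Displacement-phase metrics for one segmented trial."""
    window = (events.t_grasp, events.t_release)
    rom = {k: range_of_motion(angles.t, angles.angles[k], window) for k in ROM_DOFS}
    durations = durations or PhaseDurations.from_events(events)
    return TrialMetrics(
        condition=condition,
        rom=rom,
        trunk_comp=trunk_compensation(rom["trunk_flexion"], rom["trunk_lateral"], rom["trunk_torsion"]),
        elbow_rom=rom["elbow_flexext"],
        wrist_rom=rom["wrist_flexext"],
        finger_rom=finger_flexext_metric(rom["index_flexext"], rom["middle_flexext"]),
        movement_time=durations.movement_time,
        durations=durations,
        subject=subject,
        method=events.method,
    )


def metrics_table(metrics: list[TrialMetrics]) -> pd.DataFrame:
    """Tidy table, one row per trial."""
    return pd.DataFrame([m.to_row() for m in metrics])


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors.  The p-value is
    two-sided: the classical t approximation for n >= `exact_below`, and the
    exact permutation distribution (all n! rank permutations) below it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rho = float(rx_c @ ry_c) / denom
    rho = max(-1.0, min(1.0, rho))
    if n >= exact_below:
        if abs(rho) >= 1.0:
            return rho, 0.0
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sstats.t.sf(abs(tstat), df=n - 2))
    else:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        cross = ry_c[perms] @ rx_c  # only the cross term varies under permutation
        rhos = cross / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, min(p, 1.0)


@dataclass
class CorrelationMatrix:
    variables: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.variables)
        self.rho = np.asarray(self.rho, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("matrix shape mismatch")
        if np.max(np.abs(self.rho - self.rho.T)) > 1e-12 or np.max(np.abs(np.diag(self.rho) - 1)) > 1e-12:
            raise ValueError("rho must be symmetric with unit diagonal")
        if np.max(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)


def correlation_matrix(df: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, pv = spearman(df[variables[i]].to_numpy(), df[variables[j]].to_numpy())
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(variables=tuple(variables), rho=rho, p=p)


# ---------------------------------------------------------------------------
# Subject table
# ---------------------------------------------------------------------------

def load_subject_table() -> pd.DataFrame:
    """The bundled ten-subject demographic/clinical table."""
    with resources.files("reachkin.data").joinpath("subjects.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_subjects(table: pd.DataFrame) -> dict:
    """Column-wise medians (IQR), means and SDs plus territory group means.

    Quartiles use linear interpolation; means/SDs are the sample statistics.
    Territory groups: strokes involving the middle or posterior cerebral
    artery versus anterior cerebral artery strokes (subcortical/basal-ganglia
    rows belong to neither).
    """
    if len(table) == 0:
        raise ValueError("empty subject table")
    numeric = table.select_dtypes("number")
    summary = {
        col: {
            "median": float(numeric[col].median()),
            "iqr": (float(numeric[col].quantile(0.25)), float(numeric[col].quantile(0.75))),
            "mean": float(numeric[col].mean()),
            "sd": float(numeric[col].std(ddof=1)) if len(numeric) > 1 else 0.0,
        }
        for col in numeric.columns
    }
    out = {"columns": summary, "n": int(len(table))}
    if "territory" in table.columns and "fma_total" in table.columns:
        terr = table["territory"].astype(str)
        mca_pca = table[terr.str.contains("MCA") | terr.str.contains("PCA")]
        aca = table[terr.str.contains("ACA")]
        out["territory_groups"] = {
            "mca_pca": {"n": int(len(mca_pca)), "fma_total_mean": float(mca_pca["fma_total"].mean())},
            "aca": {"n": int(len(aca)), "fma_total_mean": float(aca["fma_total"].mean())},
        }
    return out


# ---------------------------------------------------------------------------
# Aggregation over task conditions
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    factor_means: dict[str, pd.DataFrame]
    correlations: dict[str, CorrelationMatrix] = field(default_factory=dict)


def aggregate_conditions(
    trials: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    min_per_level: int = 2,
) -> ConditionSummary:
    """Factor-level summaries and the per-arm metric correlation matrix.

    Trials are first averaged over the repetitions of each subject x
    condition cell; factor levels are the tested arm (AF/NAF), the block
    weight (BL/BW/BH) and the target height (Tab/Top).  The correlation
    matrices relate each subject's median metrics over their trials of one
    arm, so they need several subjects to be meaningful.
    """
    df = trials.copy()
    if "height" not in df.columns:
        df["height"] = df["target"].map(lambda s: "Top" if str(s).startswith("Top") else "Tab")
    cell = df.groupby(["subject", "arm", "block", "height"], as_index=False)[list(metrics)].mean()
    factor_means = {}
    for factor in ("arm", "block", "height"):
        counts = cell[factor].value_counts()
        if (counts < min_per_level).any():
            raise ValueError(f"need at least {min_per_level} trials per {factor} level")
        factor_means[factor] = cell.groupby(factor)[list(metrics)].agg(["mean", "std"])
    correlations = {}
    for arm, sub in df.groupby("arm"):
        per_subject = sub.groupby("subject")[list(metrics)].median()
        if len(per_subject) >= 3:
            try:
                correlations[arm] = correlation_matrix(per_subject, list(metrics))
            except UndefinedCorrelationError:
                pass
    return ConditionSummary(factor_means=factor_means, correlations=correlations)


def fit_condition_lmm(trials: pd.DataFrame, metric: str = "elbow_rom"):
    """Optional linear mixed-model fit: metric ~ arm + weight + height with a
    subject random intercept.  Thin wrapper over a standard fitter; not part
    of the core metric surface."""
    import statsmodels.formula.api as smf

    df = trials.copy()
    df["weight"] = df["block"].map({"BL": 0.108, "BW": 0.490, "BH": 1.008})
    model = smf.mixedlm(f"{metric} ~ C(arm) + weight + C(height)", df, groups=df["subject"])
    return model.fit(reml=True)
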