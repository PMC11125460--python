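"""Post-processing of perturbed-balance trajectories.

The analysis pipeline mirrors standard practice in perturbation studies:
discard the settling transient (first 2 s), segment the remaining record
into one-second perturbation cycles, and compute per-cycle ensemble
statistics.  On top of that ensemble sit:

* the Rudolph co-contraction index
  ``CCI(t) = (Act_L/Act_H)(Act_L + Act_H)`` per agonist/antagonist pair,
  integrated over the mean cycle for a scalar joint-stability readout;
* balance-strategy classification from the signs of Pearson correlations
  between adjacent joint moments (hip-knee, ankle-knee), with a ±0.05 dead
  band treated as non-significant;
* COP-COM stability (AP distance between the centers of pressure and mass);
* paired t-tests comparing delay conditions across the magnitude grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .control import CCI_PAIRS
from .muscle import UNIQUE_MUSCLES

DEAD_BAND = 0.05
STRATEGIES = ("ankle", "knee", "hip", "mixed")
NON_SIGNIFICANT = "non-significant"


class UndefinedCorrelation(ValueError):
    """Zero-variance input: the correlation coefficient is undefined."""


@dataclass
class CycleEnsemble:
    """cycles x within-cycle samples matrix of one signal."""

    name: str
    cycles: np.ndarray     # (n_cycles, samples_per_cycle)
    sample_rate: float     # Hz

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    def mean(self) -> np.ndarray:
        return self.cycles.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.cycles.std(axis=0, ddof=1) if self.n_cycles > 1 \
            else np.zeros(self.cycles.shape[1])


@dataclass
class CCISeries:
    pair: str
    cci: np.ndarray        # per within-cycle sample, on the mean curves
    integral: float        # trapezoid over the mean cycle, s

    def __post_init__(self) -> None:
        if np.any(self.cci < -1e-12) or np.any(self.cci > 2 + 1e-12):
            raise ValueError("CCI out of [0, 2]")
        if self.integral < -1e-12:
            raise ValueError("CCI integral must be >= 0")


@dataclass
class StrategyTimeline:
    rho_hip_knee: np.ndarray
    rho_ankle_knee: np.ndarray
    labels: list[str]      # per within-cycle sample

    def fractions(self, include_non_significant: bool = False) -> dict:
        """Time fraction per strategy; non-significant samples excluded from
        the normalization unless requested."""
        labels = self.labels if include_non_significant else \
            [x for x in self.labels if x != NON_SIGNIFICANT]
        if not labels:
            return {}
        n = len(labels)
        keys = STRATEGIES + ((NON_SIGNIFICANT,) if include_non_significant else ())
        return {s: labels.count(s) / n for s in keys}

    def dominant(self) -> frozenset:
        """Strategy (or tie set) with the largest time fraction."""
        fr = self.fractions()
        if not fr:
            return frozenset()
        best = max(fr.values())
        return frozenset(s for s, v in fr.items() if abs(v - best) < 1e-12)


@dataclass
class StabilitySeries:
    series: np.ndarray     # COP_AP - COM_AP per analyzed sample, m
    mean: float
    n_flight_excluded: int = 0


# ---------------------------------------------------------------------------

def segment_cycles(series: np.ndarray, sample_rate: float,
                   frequency: float = 1.0, discard: float = 2.0,
                   name: str = "") -> CycleEnsemble:
    """Drop the settling transient and reshape into whole cycles.

    A 10 s record at 1 Hz with a 2 s discard yields eight one-second cycles.
    """
    series = np.asarray(series, dtype=float)
    per_cycle = int(round(sample_rate / frequency))
    start = int(round(discard * sample_rate))
    avail = series.shape[0] - start
    n_cycles = avail // per_cycle
    if n_cycles < 1:
        raise ValueError("series shorter than discard + one cycle")
    chunk = series[start:start + n_cycles * per_cycle]
    return CycleEnsemble(name=name, cycles=chunk.reshape(n_cycles, per_cycle),
                         sample_rate=sample_rate)


def cci_curve(act_a: np.ndarray, act_b: np.ndarray) -> np.ndarray:
    """Rudolph co-contraction index per sample; 0 when both are silent."""
    a = np.asarray(act_a, dtype=float)
    b = np.asarray(act_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or np.any(a > 1) or np.any(b > 1):
        raise ValueError("activations must lie in [0, 1]")
    low = np.minimum(a, b)
    high = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        cci = np.where(high > 0.0, low / high * (low + high), 0.0)
    return cci


def cci_series(act_a: np.ndarray, act_b: np.ndarray, sample_rate: float,
               pair: str = "") -> CCISeries:
    """CCI over ensemble-mean activation curves plus its cycle integral."""
    cci = cci_curve(act_a, act_b)
    integral = float(np.trapezoid(cci, dx=1.0 / sample_rate))
    return CCISeries(pair=pair, cci=cci, integral=integral)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation coefficient.

    ``rho = 1/(N-1) * sum(((a_i - mu_a)/s_a) ((b_i - mu_b)/s_b))`` with
    sample standard deviations; undefined (raises) for zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length sequences, N >= 2")
    if np.std(a, ddof=1) == 0.0 or np.std(b, ddof=1) == 0.0:
        raise UndefinedCorrelation("zero variance")
    rho = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, rho))


def classify_strategy(rho_hip_knee: float, rho_ankle_knee: float,
                      dead_band: float = DEAD_BAND) -> str:
    """Strategy from the signs of the two adjacent-joint correlations.

    (+,+) ankle, (+,-) knee, (-,+) hip, (-,-) mixed; either coefficient
    inside the ±dead_band is non-significant.
    """
    for r in (rho_hip_knee, rho_ankle_knee):
        if not (-1 - 1e-9 <= r <= 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(rho_hip_knee) < dead_band or abs(rho_ankle_knee) < dead_band:
        return NON_SIGNIFICANT
    if rho_hip_knee > 0:
        return "ankle" if rho_ankle_knee > 0 else "knee"
    return "hip" if rho_ankle_knee > 0 else "mixed"


def strategy_timeline(hip: CycleEnsemble, knee: CycleEnsemble,
                      ankle: CycleEnsemble,
                      dead_band: float = DEAD_BAND) -> StrategyTimeline:
    """Per-time-step strategy labels across the cycle ensemble.

    At each within-cycle sample the correlation is taken ACROSS cycles
    (N = cycle count), which is the reading that yields a per-time-step
    coefficient from per-cycle curves.  Zero-variance samples are labelled
    non-significant.
    """
    if not (hip.cycles.shape == knee.cycles.shape == ankle.cycles.shape):
        raise ValueError("ensembles must share shape")
    ns = hip.cycles.shape[1]
    r_hk = np.full(ns, np.nan)
    r_ak = np.full(ns, np.nan)
    labels = []
    for i in range(ns):
        try:
            r_hk[i] = pearson(hip.cycles[:, i], knee.cycles[:, i])
            r_ak[i] = pearson(ankle.cycles[:, i], knee.cycles[:, i])
            labels.append(classify_strategy(r_hk[i], r_ak[i], dead_band))
        except UndefinedCorrelation:
            labels.append(NON_SIGNIFICANT)
    return StrategyTimeline(rho_hip_knee=r_hk, rho_ankle_knee=r_ak,
                            labels=labels)


def strategy_summary(timelines: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dominant strategy per condition plus overall percentage table.

    ``timelines`` maps (delay_ms, magnitude_mm) -> StrategyTimeline.
    Returns (dominant table, percentage table); dominant ties are reported
    as "A/B" sets.  Percentages are over significant samples, per delay and
    pooled, and sum to 100 per row.
    """
    delays = sorted({d for d, _ in timelines})
    mags = sorted({m for _, m in timelines})
    dom = pd.DataFrame(index=delays, columns=mags, dtype=object)
    for (d, m), tl in timelines.items():
        dom.loc[d, m] = "/".join(sorted(tl.dominant(),
                                        key=lambda s: STRATEGIES.index(s)))
    rows = {}
    def pct(tls):
        counts = {s: 0 for s in STRATEGIES}
        for tl in tls:
            for lab in tl.labels:
                if lab in counts:
                    counts[lab] += 1
        tot = sum(counts.values())
        return {s: 100.0 * c / tot if tot else np.nan
                for s, c in counts.items()}
    rows["overall"] = pct(list(timelines.values()))
    for d in delays:
        rows[d] = pct([tl for (dd, _), tl in timelines.items() if dd == d])
    overall = pd.DataFrame(rows).T
    overall.columns = [f"{s} strategy" for s in STRATEGIES]
    return dom, overall


def ankle_dominance_fraction(dominant: pd.DataFrame,
                             magnitude_threshold: float = 20.0) -> float:
    """Percent of conditions below the magnitude threshold whose dominant
    set contains the ankle strategy, rounded to the nearest integer."""
    cols = [c for c in dominant.columns if float(c) < magnitude_threshold]
    if not cols:
        raise ValueError("no conditions below threshold")
    sub = dominant[cols]
    total = sub.size
    hits = sum("ankle" in str(v).lower().split("/")
               for v in sub.to_numpy().ravel())
    return float(round(100.0 * hits / total))


def cop_com_stability(cop: np.ndarray, com_ap: np.ndarray) -> StabilitySeries:
    """Per-sample COP - COM (AP) and its mean; flight samples (NaN COP)
    are excluded and counted."""
    cop = np.asarray(cop, dtype=float)
    com_ap = np.asarray(com_ap, dtype=float)
    if cop.shape != com_ap.shape:
        raise ValueError("COP and COM series must share length")
    valid = np.isfinite(cop)
    diff = cop[valid] - com_ap[valid]
    return StabilitySeries(series=diff, mean=float(diff.mean()),
                           n_flight_excluded=int((~valid).sum()))


@dataclass
class PairedTestResult:
    comparison: str
    metric: str
    t: float
    p: float
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def paired_tests(values_a: np.ndarray, values_b: np.ndarray,
                 comparison: str = "", metric: str = "",
                 alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired t-test across the magnitude grid.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on the paired differences, df = n-1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired samples")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2 (df = n - 1)")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        raise UndefinedCorrelation("degenerate test: zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(comparison=comparison, metric=metric,
                            t=float(t), p=float(p), n=a.size, alpha=alpha)


def stats_report(metric_values: dict, alpha: float = 0.05,
                 baseline: float = 100.0) -> pd.DataFrame:
    """Paired-test table across delay conditions for several metrics.

    ``metric_values[metric][delay_ms]`` is the per-magnitude value array
    (one entry per protocol magnitude).  Each non-baseline delay is
    compared against the baseline (healthy) delay with a two-sided paired
    t-test; degenerate (zero-variance) comparisons are reported with NaN
    statistics.
    """
    rows = []
    for metric, by_delay in metric_values.items():
        delays = sorted(by_delay)
        if baseline not in by_delay:
            raise ValueError(f"baseline delay {baseline} missing for {metric}")
        for d in delays:
            if d == baseline:
                continue
            comparison = f"{baseline:g} vs {d:g} ms"
            try:
                r = paired_tests(np.asarray(by_delay[baseline], dtype=float),
                                 np.asarray(by_delay[d], dtype=float),
                                 comparison=comparison, metric=metric,
                                 alpha=alpha)
                rows.append({"metric": metric, "comparison": comparison,
                             "t": r.t, "p": r.p, "n": r.n,
                             "significant": r.significant})
            except UndefinedCorrelation:
                rows.append({"metric": metric, "comparison": comparison,
                             "t": np.nan, "p": np.nan,
                             "n": len(by_delay[baseline]),
                             "significant": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory-level drivers
# ---------------------------------------------------------------------------

def muscle_cycle_means(traj, model, frequency: float = 1.0,
                       discard: float = 2.0) -> dict[str, np.ndarray]:
    """Ensemble-mean activation curve per unique muscle, left/right
    averaged, over the post-transient cycles."""
    fs = 1.0 / traj.dt
    out = {}
    for i, name in enumerate(UNIQUE_MUSCLES):
        a = 0.5 * (traj.act[:, i] + traj.act[:, i + 9])
        out[name] = segment_cycles(a, fs, frequency, discard, name).mean()
    return out


def cci_table(traj, model, frequency: float = 1.0,
              discard: float = 2.0) -> dict[str, CCISeries]:
    """CCI series for the five analysis pairs of one trajectory."""
    means = muscle_cycle_means(traj, model, frequency, discard)
    fs = 1.0 / traj.dt
    return {f"{a}-{b}": cci_series(means[a], means[b], fs, f"{a}-{b}")
            for a, b in CCI_PAIRS}


def trajectory_strategy(traj, model, frequency: float = 1.0,
                        discard: float = 2.0) -> StrategyTimeline:
    """Strategy timeline of one trajectory from its net joint moments."""
    from .trajectory import joint_moment_series
    jm = joint_moment_series(model, traj)
    fs = 1.0 / traj.dt
    ens = {j: segment_cycles(jm[j].to_numpy(), fs, frequency, discard, j)
           for j in ("hip", "knee", "ankle")}
    return strategy_timeline(ens["hip"], ens["knee"], ens["ankle"])
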