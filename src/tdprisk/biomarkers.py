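"""Per-beat electrophysiological biomarkers and beat-indexed variability series.

Seven biomarkers summarise each paced beat:

* ``qnet``      — net charge (A/F*ms) carried over one cycle by the sum of
                  INaL, ICaL, IKr, IKs, IK1 and Ito
* ``qinward``   — mean drug/control area ratio of the inward currents ICaL
                  and INaL; equals 1 with no drug
* ``apd50/90``  — action-potential duration from upstroke to 50%/90%
                  repolarization of Vm
* ``cad50/90``  — calcium-transient duration, same rule on intracellular Ca
* ``dvmdt_max_repol`` — extremal voltage slope in the repolarization window
                  (positive values flag EAD-like re-depolarization)

The classifier consumes the raw beat-indexed series of one biomarker over
the final beats of a run (the "variability series"); no scalar variance is
taken and no rescaling is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tdprisk.cell_sim import BeatTrace

#: Currents entering the net-charge integral, in order.
QNET_CURRENTS: tuple[str, ...] = ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

#: Biomarker names, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "qNet",
    "qInward",
    "CaD50",
    "CaD90",
    "APD50",
    "APD90",
    "dVmdtMaxRepol",
)

#: ms of signal preceding the stimulus used to estimate the baseline.
BASELINE_WINDOW_MS = 10.0


@dataclass(frozen=True)
class BeatFeatures:
    """The seven per-beat biomarkers."""

    qnet: float  # A/F*ms
    qinward: float  # dimensionless
    cad50: float  # ms
    cad90: float  # ms
    apd50: float  # ms
    apd90: float  # ms
    dvmdt_max_repol: float  # mV/ms
    not_repolarized: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(
                FEATURE_NAMES,
                (
                    self.qnet,
                    self.qinward,
                    self.cad50,
                    self.cad90,
                    self.apd50,
                    self.apd90,
                    self.dvmdt_max_repol,
                ),
            )
        )


@dataclass(frozen=True)
class VariabilitySeries:
    """A beat-indexed biomarker series with provenance attached."""

    drug: str
    risk: str
    sample_id: int
    multiplier: float
    feature: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("variability series must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PoolEntry:
    """All variability series of one biomarker for one drug."""

    drug: str
    risk: str
    values: np.ndarray  # (n_series, length)
    sample_ids: np.ndarray  # (n_series,)
    multipliers: np.ndarray  # (n_series,)


class VariabilityPool:
    """Keyed store of variability series: one matrix of series per drug.

    The same container backs training pools, test pools and synthetic
    pools, so downstream stages are format-blind.
    """

    def __init__(self, feature: str = "qInward"):
        self.feature = feature
        self._entries: dict[str, PoolEntry] = {}

    def add(self, entry: PoolEntry) -> None:
        self._entries[entry.drug] = entry

    def get(self, drug: str) -> PoolEntry:
        if drug not in self._entries:
            raise KeyError(f"pool holds no series for drug {drug!r}")
        return self._entries[drug]

    @property
    def drugs(self) -> list[str]:
        return list(self._entries)

    def n_series(self) -> int:
        return sum(e.values.shape[0] for e in self._entries.values())

    def save(self, path: str) -> None:
        arrays = {"__feature__": np.array([self.feature])}
        for drug, e in self._entries.items():
            arrays[f"{drug}__values"] = e.values
            arrays[f"{drug}__risk"] = np.array([e.risk])
            arrays[f"{drug}__sample_ids"] = e.sample_ids
            arrays[f"{drug}__multipliers"] = e.multipliers
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "VariabilityPool":
        with np.load(path, allow_pickle=False) as data:
            pool = cls(feature=str(data["__feature__"][0]))
            drugs = {k.split("__")[0] for k in data.files if "__values" in k}
            for drug in sorted(drugs):
                pool.add(
                    PoolEntry(
                        drug=drug,
                        risk=str(data[f"{drug}__risk"][0]),
                        values=data[f"{drug}__values"],
                        sample_ids=data[f"{drug}__sample_ids"],
                        multipliers=data[f"{drug}__multipliers"],
                    )
                )
        return pool


def series_to_long_frame(series_list):
    """Long-format table (drug, risk, sample_id, multiplier, feature, beat,
    value) from an iterable of :class:`VariabilitySeries`."""
    import pandas as pd

    rows = []
    for s in series_list:
        for beat, value in enumerate(s.values, start=1):
            rows.append(
                (s.drug, s.risk, s.sample_id, s.multiplier, s.feature, beat, value)
            )
    return pd.DataFrame(
        rows,
        columns=["drug", "risk", "sample_id", "multiplier", "feature", "beat", "value"],
    )


def qnet(beat: BeatTrace) -> float:
    """Trapezoidal integral over the beat of the six summed currents (A/F*ms)."""
    for name in QNET_CURRENTS:
        if name not in beat.currents:
            raise ValueError(f"beat is missing current trace {name!r}")
    total = sum(beat.currents[name] for name in QNET_CURRENTS)
    return float(np.trapezoid(total, beat.t))


def _auc(beat: BeatTrace, name: str) -> float:
    return float(np.trapezoid(beat.current(name), beat.t))


def qinward(drug_beat: BeatTrace, control_beat: BeatTrace) -> float:
    """Mean drug/control AUC ratio of the inward currents ICaL and INaL.

    AUCs are integrals of the signed (inward-negative) currents, so the
    ratio of two negative areas is positive; the control beat must carry
    nonzero area in both currents.
    """
    if drug_beat.t.shape != control_beat.t.shape or not np.allclose(
        drug_beat.t, control_beat.t
    ):
        raise ValueError("drug and control beats must share the time grid")
    ratios = []
    for name in ("ICaL", "INaL"):
        a_ctrl = _auc(control_beat, name)
        if a_ctrl == 0.0:
            raise ZeroDivisionError(f"control AUC of {name} is zero; qInward undefined")
        ratios.append(_auc(drug_beat, name) / a_ctrl)
    return float(0.5 * sum(ratios))


def _upstroke_index(signal: np.ndarray) -> int:
    """Sample index of the upstroke: argmax of the first difference."""
    return int(np.argmax(np.diff(signal)))


def duration_at_fraction(
    t: np.ndarray, signal: np.ndarray, fraction: float
) -> tuple[float, bool]:
    """Time (ms) from the upstroke to ``fraction`` recovery toward baseline.

    Baseline is the diastolic value around the stimulus at t = 0: the lower
    of the first sample (pre-stimulus) and the mean of the final 10 ms of
    the beat (the 10 ms preceding the next stimulus at steady state); taking
    the minimum keeps the baseline diastolic when a beat fails to
    repolarize before the cycle ends.  The threshold is ``peak -
    fraction*(peak - baseline)`` and the crossing is located by linear
    interpolation between samples.  Returns ``(duration, not_repolarized)``;
    when the signal never crosses before the end of the beat the sentinel
    flag is set and the duration is the time remaining from upstroke to
    beat end.
    """
    t = np.asarray(t, float)
    signal = np.asarray(signal, float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    dt = t[1] - t[0]
    n_base = max(1, int(round(BASELINE_WINDOW_MS / dt)))
    baseline = min(float(signal[0]), float(signal[-n_base:].mean()))
    iu = _upstroke_index(signal)
    t_up = t[iu]
    after = signal[iu:]
    peak = float(after.max())
    thr = peak - fraction * (peak - baseline)
    ipk = iu + int(np.argmax(after))
    seg = signal[ipk:]
    below = np.where(seg <= thr)[0]
    if len(below) == 0 or below[0] == 0:
        if len(below) == 0:
            return float(t[-1] - t_up), True
        return float(t[ipk] - t_up), False
    j = ipk + below[0]
    # linear interpolation between samples j-1 (above) and j (at/below)
    s0, s1 = signal[j - 1], signal[j]
    frac = (s0 - thr) / (s0 - s1) if s0 != s1 else 0.0
    t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    return float(t_cross - t_up), False


def dvmdt_max_repol(
    beat: BeatTrace, window: tuple[float, float] = (0.3, 0.9)
) -> float:
    """Extremal Vm slope (mV/ms) within the repolarization window.

    The window spans the APD crossings at the two ``window`` fractions
    (default 30% to 90% repolarization).  The value is the maximum
    first-difference quotient: negative on normal monotone repolarization,
    positive when the membrane re-depolarizes (EAD-like behaviour).
    """
    lo, hi = window
    d_lo, _ = duration_at_fraction(beat.t, beat.vm, lo)
    d_hi, _ = duration_at_fraction(beat.t, beat.vm, hi)
    iu = _upstroke_index(beat.vm)
    t_up = beat.t[iu]
    t0, t1 = t_up + d_lo, t_up + d_hi
    mask = (beat.t[:-1] >= t0) & (beat.t[1:] <= t1)
    if not np.any(mask):
        raise ValueError("empty repolarization window")
    slopes = np.diff(beat.vm) / np.diff(beat.t)
    return float(slopes[mask].max())


def beat_features(drug_beat: BeatTrace, control_beat: BeatTrace) -> BeatFeatures:
    """All seven biomarkers for one drug beat paired with its control beat."""
    if drug_beat.cai is None or len(drug_beat.cai) == 0:
        raise ValueError("beat is missing the intracellular Ca trace")
    apd50, nr1 = duration_at_fraction(drug_beat.t, drug_beat.vm, 0.5)
    apd90, nr2 = duration_at_fraction(drug_beat.t, drug_beat.vm, 0.9)
    cad50, nr3 = duration_at_fraction(drug_beat.t, drug_beat.cai, 0.5)
    cad90, nr4 = duration_at_fraction(drug_beat.t, drug_beat.cai, 0.9)
    return BeatFeatures(
        qnet=qnet(drug_beat),
        qinward=qinward(drug_beat, control_beat),
        cad50=cad50,
        cad90=cad90,
        apd50=apd50,
        apd90=apd90,
        dvmdt_max_repol=dvmdt_max_repol(drug_beat),
        not_repolarized=nr1 or nr2 or nr3 or nr4,
    )


def variability_series(
    features: list[BeatFeatures],
    window: int = 500,
    *,
    drug: str = "",
    risk: str = "high",
    sample_id: int = 0,
    multiplier: float = 1.0,
) -> dict[str, VariabilitySeries]:
    """Final-``window`` beat-indexed series, one per biomarker, untransformed.

    With N beats of features and window w, the series covers beats
    N-w+1 .. N (beats 501-1000 for the standard 1,000-beat run).
    """
    n = len(features)
    if n < window:
        raise ValueError(f"need >= {window} beats of features, got {n}")
    tail = features[n - window :]
    out = {}
    for name in FEATURE_NAMES:
        values = np.array([f.as_dict()[name] for f in tail])
        out[name] = VariabilitySeries(
            drug=drug,
            risk=risk,
            sample_id=sample_id,
            multiplier=multiplier,
            feature=name,
            values=values,
        )
    return out
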