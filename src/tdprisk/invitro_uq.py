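"""Dose-inhibition parsing, the Hill block model, and Bayesian (IC50, h) sampling.

In-vitro safety-pharmacology screens report, per drug and per cardiac ion
channel, the fractional current inhibition at a handful of drug
concentrations.  The block is summarised by a Hill curve

    block(D) = 1 / (1 + (IC50 / D)^h)

with half-inhibitory concentration ``IC50`` (nM) and Hill coefficient ``h``
(the log-slope at IC50).  Because a few noisy points constrain (IC50, h)
only weakly, drug-block simulation consumes an *ensemble* of posterior
samples rather than a single fit: this module draws that ensemble with an
affine-invariant MCMC sampler under explicit priors, and expands it into
per-channel block sets at multiples of the clinical Cmax.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import emcee

logger = logging.getLogger(__name__)

#: The seven CiPA ion channels, in canonical order.
CHANNELS: tuple[str, ...] = ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

# Priors: log-uniform IC50 over [1e-3, 1e6] nM, uniform h over (0, 10],
# log-uniform residual sd over [1e-4, 1].
_LOG10_IC50_LO, _LOG10_IC50_HI = -3.0, 6.0
_H_LO, _H_HI = 0.0, 10.0
_LOG10_SIG_LO, _LOG10_SIG_HI = -4.0, 0.0

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class DoseResponseRecord:
    """One measured (drug, channel, concentration, fractional block) point."""

    drug: str
    channel: str
    concentration: float  # nM, > 0
    block: float  # fraction in [0, 1]
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; must be one of {CHANNELS}"
            )
        if not self.concentration > 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        if not 0.0 <= self.block <= 1.0:
            raise ValueError(f"block must be in [0, 1], got {self.block}")


@dataclass(frozen=True)
class HillSample:
    """One posterior draw of (IC50, h) for a drug x channel pair."""

    drug: str
    channel: str
    ic50: float  # nM, > 0
    h: float  # dimensionless, > 0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError("ic50 must be > 0")
        if not self.h > 0:
            raise ValueError("h must be > 0")


@dataclass(frozen=True)
class DrugInfo:
    """Drug metadata: clinical free Cmax, TdP risk class, train/test split."""

    name: str
    cmax: float  # nM
    risk: str  # high | intermediate | low
    split: str  # train | test

    def __post_init__(self) -> None:
        if self.risk not in ("high", "intermediate", "low"):
            raise ValueError(f"risk must be high/intermediate/low, got {self.risk!r}")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be train/test, got {self.split!r}")


def hill_block(ic50: float, h: float, d: float) -> float:
    """Fractional channel block at drug concentration ``d`` (nM).

    ``1 / (1 + (ic50/d)^h)``; defined as 0 at d = 0 (no drug, no block).
    """
    if not ic50 > 0:
        raise ValueError("ic50 must be > 0")
    if not h > 0:
        raise ValueError("h must be > 0")
    if d < 0:
        raise ValueError("concentration d must be >= 0")
    if d == 0:
        return 0.0
    # work in logs to avoid overflow at extreme ratios
    z = h * (math.log(ic50) - math.log(d))
    if z > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def _hill_block_vec(ic50: np.ndarray, h: np.ndarray, d: float) -> np.ndarray:
    if d == 0:
        return np.zeros(np.broadcast(ic50, h).shape)
    z = h * (np.log(ic50) - np.log(d))
    return 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))


def parse_dose_response(path: str) -> list[DoseResponseRecord]:
    """Read a delimited dose-response table into records.

    Expected CSV header: ``drug, channel, conc_nM, block`` (optional
    ``replicate``).  Blocks reported as percentages are auto-detected per
    file (any value > 1.5 implies the percent dialect) and divided by 100
    with a logged warning.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    raw_blocks = []
    for row in rows:
        try:
            raw_blocks.append(float(row["block"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"bad block value in row {rows.index(row) + 1}: {exc}")
    percent = any(b > 1.5 for b in raw_blocks)
    if percent:
        logger.warning(
            "%s: block values > 1.5 found; interpreting the block column as percent",
            path,
        )
    records = []
    for i, row in enumerate(rows, start=1):
        channel = row["channel"].strip()
        if channel not in CHANNELS:
            raise ValueError(f"row {i}: unknown channel {channel!r}")
        conc = float(row["conc_nM"])
        if conc <= 0:
            raise ValueError(f"row {i}: non-positive concentration {conc}")
        block = float(row["block"]) / (100.0 if percent else 1.0)
        records.append(
            DoseResponseRecord(
                drug=row["drug"].strip(),
                channel=channel,
                concentration=conc,
                block=min(max(block, 0.0), 1.0),
                replicate=int(row.get("replicate") or 0),
            )
        )
    return records


def write_hill_samples(samples: list[HillSample], path: str) -> None:
    """Write samples as CSV with columns drug, channel, sample_id, ic50_nM, h."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["drug", "channel", "sample_id", "ic50_nM", "h"])
        counters: dict[tuple[str, str], int] = {}
        for s in samples:
            key = (s.drug, s.channel)
            sid = counters.get(key, 0)
            counters[key] = sid + 1
            w.writerow([s.drug, s.channel, sid, repr(s.ic50), repr(s.h)])


def read_hill_samples(path: str) -> list[HillSample]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [
            HillSample(
                drug=r["drug"],
                channel=r["channel"],
                ic50=float(r["ic50_nM"]),
                h=float(r["h"]),
            )
            for r in reader
        ]


def _log_posterior(theta: np.ndarray, conc: np.ndarray, block: np.ndarray) -> float:
    log10_ic50, h, log10_sig = theta
    if not (_LOG10_IC50_LO <= log10_ic50 <= _LOG10_IC50_HI):
        return -np.inf
    if not (_H_LO < h <= _H_HI):
        return -np.inf
    if not (_LOG10_SIG_LO <= log10_sig <= _LOG10_SIG_HI):
        return -np.inf
    sig = 10.0**log10_sig
    z = h * (log10_ic50 * np.log(10.0) - np.log(conc))
    pred = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
    resid = block - pred
    n = resid.size
    return float(-0.5 * np.sum(resid**2) / sig**2 - n * np.log(sig))


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter; chains shaped (n_steps, n_chains, n_params)."""
    n, m, p = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:half], chains[half : 2 * half]], axis=1)
    # segs: (half, 2m, p)
    means = segs.mean(axis=0)
    variances = segs.var(axis=0, ddof=1)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


@dataclass
class HillFitResult:
    """Posterior sample set with convergence diagnostics attached."""

    samples: list[HillSample]
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]


def fit_hill_samples(
    records: list[DoseResponseRecord],
    n_samples: int,
    seed: int,
    *,
    n_walkers: int = 16,
    burn_in: int = 1500,
) -> HillFitResult:
    """Draw ``n_samples`` posterior (IC50, h) pairs for one drug x channel.

    Likelihood: independent Gaussian residuals on fractional block with an
    inferred noise scale.  Priors: log-uniform IC50 over [1e-3, 1e6] nM,
    uniform h over (0, 10], log-uniform noise sd.  Sampling uses an
    affine-invariant ensemble (16 walkers, 1,500 burn-in steps), thinned to
    exactly ``n_samples`` draws.  Split-R-hat is reported on the result; a
    value above 1.05 attaches a warning but does not raise.
    """
    if not records:
        raise ValueError("no records given")
    drugs = {r.drug for r in records}
    channels = {r.channel for r in records}
    if len(drugs) != 1 or len(channels) != 1:
        raise ValueError(
            f"records must cover exactly one drug x channel, got {drugs} x {channels}"
        )
    conc = np.array([r.concentration for r in records], dtype=float)
    block = np.array([r.block for r in records], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need measurements at >= 3 distinct concentrations")

    rng = np.random.RandomState(seed)
    # initialise walkers in a tight ball around a coarse grid optimum of the
    # Hill fit; scattered starts mix too slowly within the burn-in budget
    log_c = np.log10(conc)
    grid_ic50 = np.linspace(log_c.min() - 1.5, log_c.max() + 1.5, 40)
    grid_h = np.linspace(0.3, 5.0, 20)
    best, best_sse = (grid_ic50[0], 1.0), np.inf
    for gi in grid_ic50:
        for gh in grid_h:
            z = gh * (gi * np.log(10.0) - np.log(conc))
            pred = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
            sse = float(np.sum((block - pred) ** 2))
            if sse < best_sse:
                best, best_sse = (gi, gh), sse
    sig0 = np.log10(max(np.sqrt(best_sse / max(len(block), 1)), 2e-4))
    p0 = np.column_stack(
        [
            (best[0] + 0.05 * rng.randn(n_walkers)).clip(_LOG10_IC50_LO, _LOG10_IC50_HI),
            (best[1] + 0.05 * rng.randn(n_walkers)).clip(0.05, _H_HI),
            (sig0 + 0.1 * rng.randn(n_walkers)).clip(_LOG10_SIG_LO, _LOG10_SIG_HI),
        ]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 3, _log_posterior, args=(conc, block))
    state = emcee.State(p0, random_state=np.random.mtrand.RandomState(seed + 1).get_state())
    state = sampler.run_mcmc(state, burn_in, progress=False)
    sampler.reset()
    n_main = max(burn_in, (n_samples + n_walkers - 1) // n_walkers)
    sampler.run_mcmc(state, n_main, progress=False)

    chain = sampler.get_chain()  # (n_main, n_walkers, 3)
    rhat = _split_rhat(chain)
    rhat_map = {"log10_ic50": float(rhat[0]), "h": float(rhat[1]), "log10_sigma": float(rhat[2])}
    converged = bool(np.all(rhat[:2] < RHAT_THRESHOLD))
    if not converged:
        warnings.warn(
            f"Hill posterior sampler may not have converged: split-R-hat {rhat_map}",
            RuntimeWarning,
        )

    flat = chain.reshape(-1, 3)
    # evenly thin the flattened post-burn-in chain down to n_samples
    idx = np.linspace(0, len(flat) - 1, n_samples).round().astype(int)
    drug, channel = records[0].drug, records[0].channel
    samples = [
        HillSample(drug=drug, channel=channel, ic50=float(10.0 ** t[0]), h=float(t[1]))
        for t in flat[idx]
    ]
    return HillFitResult(samples=samples, rhat=rhat_map, converged=converged)


def sample_block_sets(
    samples: dict[str, list[HillSample]],
    cmax: float,
    multipliers: list[float],
) -> list[dict[str, float]]:
    """Expand per-channel Hill samples into 7-channel block sets.

    For every (sample index, Cmax multiplier) pair, evaluates the Hill block
    at ``d = multiplier * cmax`` on each measured channel; channels with no
    measurement are unblocked (0).  Output length = n_samples x
    len(multipliers), ordered multiplier-major then sample index.
    """
    if cmax <= 0:
        raise ValueError("cmax must be > 0")
    if not multipliers:
        raise ValueError("multipliers must be non-empty")
    if any(m < 0 for m in multipliers):
        raise ValueError("multipliers must be non-negative")
    for ch in samples:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
    lengths = {ch: len(s) for ch, s in samples.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"all channels must share n_samples, got {lengths}")
    n = next(iter(lengths.values())) if lengths else 0
    out: list[dict[str, float]] = []
    for mult in multipliers:
        d = mult * cmax
        for i in range(n):
            blocks = {ch: 0.0 for ch in CHANNELS}
            for ch, chain in samples.items():
                s = chain[i]
                blocks[ch] = hill_block(s.ic50, s.h, d)
            out.append(blocks)
    return out
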