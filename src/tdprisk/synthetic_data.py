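"""Synthetic inputs for every pipeline stage: dose-response tables with known
ground-truth Hill parameters, class-conditioned variability pools, and the
28-drug CiPA reference fixture.

The variability-pool generator emits AR(1) series with class-dependent mean,
within-class standard deviation, lag-1 autocorrelation and optional
even/odd-beat alternans, plus a per-drug random offset.  That is the minimal
structure carrying beat-to-beat information for the classifier to exploit;
it makes no claim of physiological fidelity (see docs/methods.md) but lets
the classifier and evaluator be exercised end-to-end without hours of
myocyte simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tdprisk.invitro_uq import DoseResponseRecord, DrugInfo, hill_block
from tdprisk.biomarkers import PoolEntry, VariabilityPool

# Default class-conditional series structure on the qInward scale.  A
# no-drug beat has qInward 1.  Mean level: calcium-channel blockers
# (typically low risk) depress the inward charge most, predominantly-hERG
# blockers (high risk) least.  Beat-to-beat dynamics: hERG block at slow
# pacing destabilises repolarization, giving the high-risk class an
# even/odd-beat alternans component; strong multi-channel block gives the
# low-risk class larger, weakly correlated fluctuation; the intermediate
# class sits between with smooth, strongly autocorrelated drift.
_DEFAULT_CLASS_PARAMS = {
    "high": {"mean": 0.95, "sd": 0.03, "autocorrelation": 0.5, "alternans": 0.05},
    "intermediate": {"mean": 0.82, "sd": 0.02, "autocorrelation": 0.7, "alternans": 0.0},
    "low": {"mean": 0.62, "sd": 0.04, "autocorrelation": 0.3, "alternans": 0.0},
}


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Per-risk-class series statistics for the synthetic variability pools.

    Each class carries a mean level, within-class (stationary) standard
    deviation, lag-1 autocorrelation, and an optional alternans amplitude
    (even/odd-beat alternation); ``drug_offset_sd`` shifts each drug's mean
    by a random per-drug offset.
    """

    class_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_CLASS_PARAMS.items()
    })
    drug_offset_sd: float = 0.02  # per-drug random shift of the mean

    def __post_init__(self) -> None:
        for cls, p in self.class_params.items():
            if p["sd"] < 0:
                raise ValueError(f"sd for class {cls!r} must be >= 0")
            if not -1.0 < p["autocorrelation"] < 1.0:
                raise ValueError(f"autocorrelation for class {cls!r} must lie in (-1, 1)")


def gen_dose_response(
    true_ic50: float,
    true_h: float,
    doses,
    noise_sd: float,
    n_rep: int,
    seed: int,
    *,
    drug: str = "synthetic",
    channel: str = "IKr",
) -> list[DoseResponseRecord]:
    """Hill-model dose-response records with Gaussian noise, clipped to [0,1]."""
    doses = list(doses)
    if not doses:
        raise ValueError("doses must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_rep):
        for d in doses:
            block = hill_block(true_ic50, true_h, d)
            if noise_sd > 0:
                block = float(np.clip(block + rng.normal(0.0, noise_sd), 0.0, 1.0))
            records.append(
                DoseResponseRecord(
                    drug=drug, channel=channel, concentration=d, block=block, replicate=rep
                )
            )
    return records


def gen_variability_pool(
    drugs: list[DrugInfo],
    spec: SyntheticClassSpec,
    per_drug: int,
    length: int,
    seed: int,
    *,
    multipliers=(1.0, 2.0, 3.0, 4.0),
    feature: str = "qInward",
) -> VariabilityPool:
    """Class-conditioned AR(1) variability pool, ``per_drug`` series per drug.

    Each series is a stationary AR(1) process around the drug's mean level
    (class mean + per-drug offset) with the spec's lag-1 autocorrelation and
    within-class standard deviation, plus optional alternans.  Series are
    spread evenly across the Cmax multipliers for provenance.  Seeded and
    bit-reproducible.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    pool = VariabilityPool(feature=feature)
    for drug in drugs:
        if drug.risk not in spec.class_params:
            raise ValueError(f"unknown risk label {drug.risk!r}")
        p = spec.class_params[drug.risk]
        phi = p["autocorrelation"]
        mu = p["mean"] + rng.normal(0.0, spec.drug_offset_sd)
        sd = p["sd"]
        # innovations scaled for a stationary marginal sd equal to `sd`
        eps_sd = sd * np.sqrt(1.0 - phi**2)
        x = np.empty((per_drug, length), dtype=np.float32)
        state = rng.normal(0.0, sd, size=per_drug)
        for t in range(length):
            state = phi * state + rng.normal(0.0, eps_sd, size=per_drug)
            x[:, t] = state
        x += mu
        if p.get("alternans"):
            x += p["alternans"] * ((-1.0) ** np.arange(length))[None, :].astype(
                np.float32
            )
        mults = np.asarray(multipliers, dtype=float)
        pool.add(
            PoolEntry(
                drug=drug.name,
                risk=drug.risk,
                values=x,
                sample_ids=np.arange(per_drug) % max(1, per_drug // len(mults)),
                multipliers=mults[
                    (np.arange(per_drug) * len(mults)) // max(per_drug, 1)
                ],
            )
        )
    return pool


#: (name, cmax nM, risk, split) for the 28 CiPA reference drugs.
_DRUG_TABLE = [
    ("Bepridil", 33.0, "high", "train"),
    ("Dofetilide", 2.0, "high", "train"),
    ("Sotalol", 1439.0, "high", "train"),
    ("Quinidine", 3237.0, "high", "train"),
    ("Cisapride", 2.6, "intermediate", "train"),
    ("Chlorpromazine", 38.0, "intermediate", "train"),
    ("Ondansetron", 139.0, "intermediate", "train"),
    ("Terfenadine", 4.0, "intermediate", "train"),
    ("Diltiazem", 122.0, "low", "train"),
    ("Mexiletine", 4129.0, "low", "train"),
    ("Ranolazine", 1948.2, "low", "train"),
    ("Verapamil", 81.0, "low", "train"),
    ("Azimilide", 70.0, "high", "test"),
    ("Disopyramide", 742.0, "high", "test"),
    ("Ibutilide", 100.0, "high", "test"),
    ("Vandetanib", 255.4, "high", "test"),
    ("Astemizole", 0.26, "intermediate", "test"),
    ("Clarithromycin", 1206.0, "intermediate", "test"),
    ("Clozapine", 71.0, "intermediate", "test"),
    ("Domperidone", 19.0, "intermediate", "test"),
    ("Droperidol", 6.33, "intermediate", "test"),
    ("Pimozide", 0.431, "intermediate", "test"),
    ("Risperidone", 1.81, "intermediate", "test"),
    ("Loratadine", 0.45, "low", "test"),
    ("Metoprolol", 1800.0, "low", "test"),
    ("Nifedipine", 7.7, "low", "test"),
    ("Nitrendipine", 3.02, "low", "test"),
    ("Tamoxifen", 21.0, "low", "test"),
]


def fixture_drugs() -> list[DrugInfo]:
    """The 28 CiPA reference drugs: free Cmax (nM), risk class, train/test split."""
    return [DrugInfo(name=n, cmax=c, risk=r, split=s) for n, c, r, s in _DRUG_TABLE]
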