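"""Synthetic cohorts with planted, ground-truth-known monotone structure.

The generator emulates a block-design associative-learning fMRI experiment:
eight iterations of four sequential 27-s conditions (Encoding, Post-Encoding
Rest, Retrieval, Post-Retrieval Rest) sampled at TR = 3 s, i.e. 9 volumes per
epoch and 288 volumes in total at defaults, with nine object-location
associations probed per Retrieval epoch.

Signal model
------------
Each epoch has one shared latent factor f_t ~ N(0, 1) (i.i.d. volumes within
the epoch by default; optional AR(1)); region r's signal in that epoch is

    x[r, t] = baseline + c_r * f_t + noise_sd * eps[r, t]

with independent Gaussian noise. The loading c_r is ``base_coupling`` (minus
``group_coupling_offset`` for the patient-like group), plus
``iteration * drift_per_iteration`` for designated hub nodes. Raising a
node's loading strengthens all its edges, so hub nodes drift monotonically
upward in centrality — the planted ground truth that the trend screen is
asked to recover. Under this one-factor model the population correlation of
regions i and j is c_i c_j / sqrt((c_i^2 + sd^2)(c_j^2 + sd^2)).

Behavior model
--------------
Retrieval follows an item-level all-or-none learning process: each of the
nine items is learnable with probability ``behavior_asymptote`` (per group),
and a learnable item is acquired on any iteration with probability
1 - exp(-behavior_rate); once acquired it stays correct (an optional
``lapse_prob`` re-introduces occasional recall failures, default off). The
expected proportion correct is then exactly the negatively accelerated
curve p_t = asymptote * (1 - exp(-rate * t)), and realized trajectories are
weakly monotone up to lapses — the empirical signature of associative
learning. A configurable fraction of participants per group are
"non-monotone performers": their per-iteration success schedule is randomly
permuted and items are redrawn independently each iteration, destroying the
planted behavioral trend.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from monoconn.epochs import DEFAULT_CONDITIONS, EpochDesign, ParcellatedTimeSeries
from monoconn.errors import ConfigurationError

GROUPS = ("control", "patient")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort; validated on construction."""

    n_regions: int = 246
    n_iterations: int = 8
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    volumes_per_epoch: int = 9
    n_participants_per_group: int = 10
    n_items: int = 9
    hub_nodes: frozenset[int] = field(default_factory=frozenset)
    drift_per_iteration: float = 0.0
    drift_conditions: tuple[str, ...] | None = None  # None = all conditions
    base_coupling: float = 0.4
    group_coupling_offset: float = 0.1
    behavior_asymptote: dict[str, float] = field(
        default_factory=lambda: {"control": 0.92, "patient": 0.75}
    )
    behavior_rate: float = 0.9
    lapse_prob: float = 0.0
    nonmonotone_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.1, "patient": 0.4}
    )
    noise_sd: float = 0.6
    baseline: float = 1000.0
    ar1_phi: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hub_nodes", frozenset(self.hub_nodes))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.drift_conditions is not None:
            object.__setattr__(self, "drift_conditions", tuple(self.drift_conditions))
            unknown = set(self.drift_conditions) - set(self.conditions)
            if unknown:
                raise ConfigurationError(
                    f"drift_conditions {sorted(unknown)} not in conditions"
                )
        for name in ("n_regions", "n_iterations", "volumes_per_epoch",
                     "n_participants_per_group", "n_items"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.volumes_per_epoch < 2:
            raise ConfigurationError("volumes_per_epoch must be >= 2")
        if any(i < 0 or i >= self.n_regions for i in self.hub_nodes):
            raise ConfigurationError("hub_nodes must be valid region indices")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.ar1_phi < 1:
            raise ConfigurationError("ar1_phi must be in [0, 1)")
        for group in GROUPS:
            p = self.behavior_asymptote.get(group)
            if p is None or not 0 <= p <= 1:
                raise ConfigurationError(
                    f"behavior_asymptote[{group!r}] must be a probability in [0, 1]"
                )
            f = self.nonmonotone_fraction.get(group)
            if f is None or not 0 <= f <= 1:
                raise ConfigurationError(
                    f"nonmonotone_fraction[{group!r}] must be a probability in [0, 1]"
                )
        if self.behavior_rate < 0:
            raise ConfigurationError("behavior_rate must be non-negative")
        if not 0 <= self.lapse_prob <= 1:
            raise ConfigurationError("lapse_prob must be a probability in [0, 1]")
        # every loading any node can take must define a valid correlation structure
        for group in GROUPS:
            base = self.group_base_coupling(group)
            if not 0 <= base < 1:
                raise ConfigurationError(
                    f"base_coupling - group_coupling_offset = {base:.4g} for group "
                    f"{group!r} is outside [0, 1); adjust base_coupling or "
                    "group_coupling_offset"
                )
            if self.hub_nodes:
                for it in (1, self.n_iterations):
                    c = base + it * self.drift_per_iteration
                    if not 0 <= c < 1:
                        raise ConfigurationError(
                            f"hub loading {c:.4g} at iteration {it} for group "
                            f"{group!r} is outside [0, 1); adjust "
                            "drift_per_iteration or base_coupling"
                        )

    @property
    def total_volumes(self) -> int:
        return self.volumes_per_epoch * self.n_iterations * len(self.conditions)

    def group_base_coupling(self, group: str) -> float:
        if group not in GROUPS:
            raise ConfigurationError(f"unknown group {group!r}; expected {GROUPS}")
        return self.base_coupling - (
            self.group_coupling_offset if group == "patient" else 0.0
        )

    def design(self) -> EpochDesign:
        return EpochDesign.block_design(
            conditions=self.conditions,
            n_iterations=self.n_iterations,
            volumes_per_epoch=self.volumes_per_epoch,
        )

    def loading(self, region: int, group: str, condition: str, iteration: int) -> float:
        """Latent-factor loading of ``region`` in one epoch."""
        c = self.group_base_coupling(group)
        drifting = self.drift_conditions is None or condition in self.drift_conditions
        if region in self.hub_nodes and drifting:
            c += iteration * self.drift_per_iteration
        return c


@dataclass
class BehavioralRecord:
    """Per-iteration binary item outcomes (n_iterations x n_items)."""

    outcomes: np.ndarray

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be 2-D (iterations x items)")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary")

    @property
    def proportion_correct(self) -> np.ndarray:
        """Iteration-ordered proportion-correct trajectory."""
        return self.outcomes.mean(axis=1)


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    timeseries: ParcellatedTimeSeries
    behavior: BehavioralRecord


@dataclass
class Cohort:
    participants: list[ParticipantData]
    manifest: dict
    design: EpochDesign | None = None  # file-backed design, when loaded from disk


def _ar1_colored(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Unit-variance Gaussian noise, AR(1) along the last axis when phi > 0."""
    x = rng.standard_normal(shape)
    if phi > 0:
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, shape[-1]):
            x[..., t] = phi * x[..., t - 1] + scale * x[..., t]
    return x


def generate_participant_timeseries(
    cfg: SynthConfig, group: str, rng_seed: int
) -> ParcellatedTimeSeries:
    """One participant's regions x volumes matrix under the one-factor model.

    Identical (cfg, group, rng_seed) reproduce the output bit-for-bit.
    """
    base = cfg.group_base_coupling(group)  # validates the group label
    rng = np.random.default_rng(rng_seed)
    design = cfg.design()
    X = np.full((cfg.n_regions, cfg.total_volumes), cfg.baseline, dtype=float)
    if cfg.noise_sd == 0 and base == 0 and (
        not cfg.hub_nodes or cfg.drift_per_iteration == 0
    ):
        warnings.warn(
            "noise_sd and all loadings are zero: every region is constant and "
            "downstream correlations are undefined",
            stacklevel=2,
        )
    for (cond, it), sub in design.table.groupby(
        ["condition", "iteration"], sort=False
    ):
        idx = np.sort(sub["volume_index"].to_numpy())
        nv = len(idx)
        loadings = np.array(
            [cfg.loading(r, group, cond, int(it)) for r in range(cfg.n_regions)]
        )
        factor = _ar1_colored(rng, (nv,), cfg.ar1_phi)
        noise = _ar1_colored(rng, (cfg.n_regions, nv), cfg.ar1_phi)
        X[:, idx] += loadings[:, None] * factor[None, :] + cfg.noise_sd * noise
    return ParcellatedTimeSeries(
        X, region_labels=[f"R{r:03d}" for r in range(cfg.n_regions)], group=group
    )


def learning_curve(cfg: SynthConfig, group: str) -> np.ndarray:
    """Expected per-iteration success probability p_t = a * (1 - exp(-rate * t))."""
    t = np.arange(1, cfg.n_iterations + 1, dtype=float)
    return cfg.behavior_asymptote[group] * -np.expm1(-cfg.behavior_rate * t)


def generate_behavior(cfg: SynthConfig, group: str, rng_seed: int) -> BehavioralRecord:
    """One participant's per-iteration item outcomes; seeds reproduce exactly.

    Monotone performers follow the all-or-none acquisition process (learned
    items stay learned, modulo ``lapse_prob``); non-monotone performers get a
    permuted success schedule with items redrawn independently per iteration.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; expected {GROUPS}")
    rng = np.random.default_rng(rng_seed)
    if rng.random() < cfg.nonmonotone_fraction[group]:
        p = learning_curve(cfg, group)[rng.permutation(cfg.n_iterations)]
        draws = rng.random((cfg.n_iterations, cfg.n_items))
        return BehavioralRecord((draws < p[:, None]).astype(int))
    q = float(-np.expm1(-cfg.behavior_rate))  # per-iteration acquisition prob
    learnable = rng.random(cfg.n_items) < cfg.behavior_asymptote[group]
    if q > 0:
        acquired_at = rng.geometric(q, size=cfg.n_items)
    else:
        acquired_at = np.full(cfg.n_items, np.iinfo(np.int64).max)
    t = np.arange(1, cfg.n_iterations + 1)[:, None]
    outcomes = (learnable[None, :] & (acquired_at[None, :] <= t)).astype(int)
    if cfg.lapse_prob > 0:
        lapses = rng.random(outcomes.shape) < cfg.lapse_prob
        outcomes[lapses] = 0
    return BehavioralRecord(outcomes)


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """A full two-group cohort plus its ground-truth manifest.

    Participant seeds are derived deterministically from ``cfg.seed``; the
    manifest records them together with the planted hub set and drift sign so
    downstream recovery analyses have an explicit oracle.
    """
    seed_rng = np.random.default_rng(cfg.seed)
    participants: list[ParticipantData] = []
    manifest_participants = []
    for group, prefix in zip(GROUPS, ("C", "P")):
        for k in range(cfg.n_participants_per_group):
            pid = f"{prefix}{k + 1:03d}"
            ts_seed = int(seed_rng.integers(0, 2**31 - 1))
            beh_seed = int(seed_rng.integers(0, 2**31 - 1))
            ts = generate_participant_timeseries(cfg, group, ts_seed)
            ts.participant_id = pid
            beh = generate_behavior(cfg, group, beh_seed)
            participants.append(ParticipantData(pid, group, ts, beh))
            manifest_participants.append(
                {"participant_id": pid, "group": group,
                 "timeseries_seed": ts_seed, "behavior_seed": beh_seed}
            )
    drift_sign = (
        0 if not cfg.hub_nodes or cfg.drift_per_iteration == 0
        else int(np.sign(cfg.drift_per_iteration))
    )
    manifest = {
        "seed": cfg.seed,
        "groups": list(GROUPS),
        "n_participants_per_group": cfg.n_participants_per_group,
        "participants": manifest_participants,
        "ground_truth": {
            "hub_nodes": sorted(cfg.hub_nodes),
            "drift_per_iteration": cfg.drift_per_iteration,
            # +1: hubness (BC) drifts up, so BC rank order drifts DOWN (toward 1)
            "hubness_trend_sign": drift_sign,
            "drift_conditions": (
                list(cfg.conditions) if cfg.drift_conditions is None
                else list(cfg.drift_conditions)
            ),
            "patient_coupling_offset": cfg.group_coupling_offset,
        },
        "config": config_to_dict(cfg),
    }
    return Cohort(participants, manifest)


def config_to_dict(cfg: SynthConfig) -> dict:
    """JSON-serializable echo of the configuration."""
    return {
        "n_regions": cfg.n_regions,
        "n_iterations": cfg.n_iterations,
        "conditions": list(cfg.conditions),
        "volumes_per_epoch": cfg.volumes_per_epoch,
        "n_participants_per_group": cfg.n_participants_per_group,
        "n_items": cfg.n_items,
        "hub_nodes": sorted(cfg.hub_nodes),
        "drift_per_iteration": cfg.drift_per_iteration,
        "drift_conditions": (
            None if cfg.drift_conditions is None else list(cfg.drift_conditions)
        ),
        "base_coupling": cfg.base_coupling,
        "group_coupling_offset": cfg.group_coupling_offset,
        "behavior_asymptote": dict(cfg.behavior_asymptote),
        "behavior_rate": cfg.behavior_rate,
        "nonmonotone_fraction": dict(cfg.nonmonotone_fraction),
        "noise_sd": cfg.noise_sd,
        "baseline": cfg.baseline,
        "ar1_phi": cfg.ar1_phi,
        "seed": cfg.seed,
    }


def config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    for key in ("conditions", "drift_conditions"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if "hub_nodes" in d:
        d["hub_nodes"] = frozenset(d["hub_nodes"])
    return SynthConfig(**d)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Serialize a cohort: per-participant matrix TSVs, design TSV, behavior
    TSV and the manifest JSON. Returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config_from_dict(cohort.manifest["config"])
    design = cfg.design()
    design.table.to_csv(outdir / "design.tsv", sep="\t", index=False)
    beh_rows = []
    for p in cohort.participants:
        labels = p.timeseries.region_labels or [
            f"R{r:03d}" for r in range(p.timeseries.n_regions)
        ]
        with open(outdir / f"timeseries_{p.participant_id}.tsv", "w") as fh:
            fh.write("region\t" + "\t".join(
                f"v{t:03d}" for t in range(p.timeseries.n_volumes)
            ) + "\n")
            for label, row in zip(labels, p.timeseries.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        for it in range(cfg.n_iterations):
            for item in range(cfg.n_items):
                beh_rows.append(
                    f"{p.participant_id}\t{p.group}\t{it + 1}\t{item}\t"
                    f"{p.behavior.outcomes[it, item]}"
                )
    with open(outdir / "behavior.tsv", "w") as fh:
        fh.write("participant\tgroup\titeration\titem\tcorrect\n")
        fh.write("\n".join(beh_rows) + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def read_cohort(indir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    import pandas as pd

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = config_from_dict(manifest["config"])
    design = None
    if (indir / "design.tsv").exists():
        design = EpochDesign(
            pd.read_csv(indir / "design.tsv", sep="\t"), conditions=cfg.conditions
        )
    beh = pd.read_csv(indir / "behavior.tsv", sep="\t")
    participants = []
    for entry in manifest["participants"]:
        pid, group = entry["participant_id"], entry["group"]
        df = pd.read_csv(indir / f"timeseries_{pid}.tsv", sep="\t")
        labels = df["region"].tolist()
        ts = ParcellatedTimeSeries(
            df.drop(columns="region").to_numpy(float),
            participant_id=pid, group=group, region_labels=labels,
        )
        sub = beh[beh["participant"] == pid].sort_values(["iteration", "item"])
        outcomes = sub["correct"].to_numpy().reshape(cfg.n_iterations, cfg.n_items)
        participants.append(ParticipantData(pid, group, ts, BehavioralRecord(outcomes)))
    return Cohort(participants, manifest, design=design)
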