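"""Synthetic discordant-twin cohort generator with ground truth.

The generator emulates the motivating study design: ``n_pairs`` monozygotic
twin pairs discordant for a systemic autoimmune disease (proband P and
unaffected co-twin U), each matched to ``n_controls_per_pair`` unrelated
controls (C) on age, sex and ethnicity, assayed on two-color arrays that
report per-probe log2 expression ratios against a universal reference.

Per probe g and sample i the simulated log2 ratio is

    y[g, i] = mu[g] + a[g, pair(i)] + s[g, set(i)] + h[g, batch(i)]
              + d[g, pair(i)] * (1 if role P else lam if role U else 0)
              + eps[g, i]

with probe baseline ``mu ~ N(0, 1)``, a per-probe twin-pair effect ``a``
shared by the two co-twins (familial correlation of expression acts gene by
gene), a per-probe matched-set effect ``s`` shared by all members of a set, a
per-probe hybridization-batch shift ``h``, and iid residual noise ``eps``.
A minority ``frac_de`` of probes carry a disease effect ``d`` whose log2
magnitude is drawn uniformly (default range 0.14-2.86, i.e. 1.1- to 7.2-fold)
with a configurable up-regulated sign fraction (default 25% up / 75% down,
mirroring the predominance of under-expression in the motivating cohort).
The unaffected twin expresses the fraction ``lam`` (the intermediacy
coefficient) of the disease effect.  Whole matched sets are assigned to
hybridization batches round-robin.  Identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .io import CohortDesign, ProbeMatrix, SampleRecord

SUBTYPE_CYCLE = ("SLE", "RA", "IIM")


@dataclass(frozen=True)
class DeltaSpec:
    """Distribution of the disease effect's log2 magnitude and sign."""

    low: float = 0.14
    high: float = 2.86
    p_up: float = 0.25

    def validate(self) -> None:
        if not (0 < self.low <= self.high):
            raise ParameterError("delta magnitude range must satisfy 0 < low <= high")
        if not (0.0 <= self.p_up <= 1.0):
            raise ParameterError("p_up must lie in [0, 1]")


@dataclass
class SimParams:
    """Simulation parameters; defaults reproduce the study's cohort layout."""

    n_pairs: int = 20
    n_controls_per_pair: int = 2
    n_probes: int = 20_000
    n_batches: int = 5
    frac_de: float = 0.005
    delta_log2: DeltaSpec = field(default_factory=DeltaSpec)
    lambda_intermediacy: float = 0.6
    sd_pair: float = 0.3
    sd_set: float = 0.2
    sd_batch: float = 0.3
    sd_resid: float = 0.4
    subtype_split: Mapping[str, int] | None = None
    subtype_effect: Mapping[str, float] | None = None
    tail_df: float | None = None
    seed: int = 0

    def resolved_split(self) -> dict[str, int]:
        if self.subtype_split is not None:
            return dict(self.subtype_split)
        if self.n_pairs == 20:
            return {"SLE": 6, "RA": 6, "IIM": 8}
        base = self.n_pairs // 3
        split = {t: base for t in SUBTYPE_CYCLE}
        for i in range(self.n_pairs - 3 * base):
            split[SUBTYPE_CYCLE[i]] += 1
        return split

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_controls_per_pair < 1 or self.n_probes < 1:
            raise ParameterError("counts must be positive")
        if self.n_batches < 1:
            raise ParameterError("n_batches must be positive")
        for name in ("sd_pair", "sd_set", "sd_batch", "sd_resid"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ParameterError("frac_de must lie in [0, 1]")
        if not (0.0 <= self.lambda_intermediacy <= 1.0):
            raise ParameterError("lambda_intermediacy must lie in [0, 1]")
        self.delta_log2.validate()
        split = self.resolved_split()
        if sum(split.values()) != self.n_pairs:
            raise ParameterError("subtype_split must sum to n_pairs")
        if self.tail_df is not None and self.tail_df <= 2:
            raise ParameterError("tail_df must exceed 2 (finite variance)")


@dataclass
class SimTruth:
    """Ground truth for recovery tests: which probes are affected and how."""

    frame: pd.DataFrame  # columns: probe_id, affected, delta_log2
    lambda_intermediacy: float
    subtype_of_pair: dict[str, str]

    @property
    def affected(self) -> np.ndarray:
        return self.frame["affected"].to_numpy(dtype=bool)

    @property
    def delta_log2(self) -> np.ndarray:
        return self.frame["delta_log2"].to_numpy(dtype=float)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def truth_fold(delta_log2: float) -> float:
    """Convert a log2 effect to the (unsigned) fold-ratio scale, ``2**delta``."""
    return float(2.0 ** np.asarray(delta_log2, dtype=float))


def _noise(rng: np.random.Generator, sd: float, size, tail_df: float | None) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    if tail_df is None:
        return rng.normal(0.0, sd, size)
    # Student-t scaled to the requested standard deviation
    scale = sd / np.sqrt(tail_df / (tail_df - 2.0))
    return rng.standard_t(tail_df, size) * scale


def simulate_cohort(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[ProbeMatrix, CohortDesign, SimTruth]:
    """Generate (matrix, design, truth) for one synthetic cohort."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_pairs = params.n_pairs
    n_ctrl = params.n_controls_per_pair
    per_set = 2 + n_ctrl
    n_samples = n_pairs * per_set
    G = params.n_probes

    # subtype assignment per pair, in declaration order
    split = params.resolved_split()
    pair_subtypes: list[str] = []
    for t in SUBTYPE_CYCLE:
        pair_subtypes.extend([t] * split.get(t, 0))
    for t in split:
        if t not in SUBTYPE_CYCLE:
            raise ParameterError(f"unknown subtype {t!r} in subtype_split")

    # design table -------------------------------------------------------
    records: list[SampleRecord] = []
    pair_idx: list[int] = []  # -1 for controls
    set_idx: list[int] = []
    batch_idx: list[int] = []
    roles: list[str] = []
    for k in range(n_pairs):
        pair_id = f"pair{k:02d}"
        set_id = f"set{k:02d}"
        batch = f"batch{k % params.n_batches}"
        subtype = pair_subtypes[k]
        age = float(np.round(rng.uniform(5.0, 45.0), 1))
        sex = "F" if rng.random() < 0.7 else "M"
        ethnicity = "Caucasian" if rng.random() < 0.95 else "Hispanic"
        members = [
            (f"tw{k:02d}P", "P", pair_id, subtype, age),
            (f"tw{k:02d}U", "U", pair_id, subtype, age),
        ]
        for c in range(n_ctrl):
            cage = float(np.round(np.clip(age + rng.uniform(-6.0, 6.0), 3.0, None), 1))
            members.append((f"ct{k:02d}{chr(97 + c)}", "C", "", "NONE", cage))
        for sid, role, pid, stype, a in members:
            records.append(
                SampleRecord(sid, role, pid, set_id, stype, batch, a, sex, ethnicity)
            )
            pair_idx.append(k if role in ("P", "U") else -1)
            set_idx.append(k)
            batch_idx.append(k % params.n_batches)
            roles.append(role)
    design = CohortDesign(records)
    pair_idx_a = np.array(pair_idx)
    set_idx_a = np.array(set_idx)
    batch_idx_a = np.array(batch_idx)
    roles_a = np.array(roles)

    # truth ---------------------------------------------------------------
    n_de = int(round(params.frac_de * G))
    affected = np.zeros(G, dtype=bool)
    if n_de:
        affected[rng.choice(G, size=n_de, replace=False)] = True
    mag = rng.uniform(params.delta_log2.low, params.delta_log2.high, G)
    sign = np.where(rng.random(G) < params.delta_log2.p_up, 1.0, -1.0)
    delta = np.where(affected, mag * sign, 0.0)

    # components ----------------------------------------------------------
    mu = rng.normal(0.0, 1.0, G)
    a = _noise(rng, params.sd_pair, (G, n_pairs), params.tail_df)
    s = _noise(rng, params.sd_set, (G, n_pairs), params.tail_df)
    h = _noise(rng, params.sd_batch, (G, params.n_batches), params.tail_df)
    eps = _noise(rng, params.sd_resid, (G, n_samples), params.tail_df)

    y = mu[:, None] + s[:, set_idx_a] + h[:, batch_idx_a] + eps
    twin = pair_idx_a >= 0
    y[:, twin] += a[:, pair_idx_a[twin]]

    # disease effect with optional per-subtype extra, on affected probes only
    extra = np.zeros(n_pairs)
    if params.subtype_effect:
        extra = np.array(
            [params.subtype_effect.get(t, 0.0) for t in pair_subtypes]
        )
    d_eff = delta[:, None] + np.where(affected[:, None], extra[None, :], 0.0)
    is_p = roles_a == "P"
    is_u = roles_a == "U"
    y[:, is_p] += d_eff[:, pair_idx_a[is_p]]
    y[:, is_u] += params.lambda_intermediacy * d_eff[:, pair_idx_a[is_u]]

    probe_ids = [f"probe{g:05d}" for g in range(G)]
    matrix = ProbeMatrix(probe_ids, design.subject_ids, y)
    truth = SimTruth(
        pd.DataFrame(
            {"probe_id": probe_ids, "affected": affected, "delta_log2": delta}
        ),
        params.lambda_intermediacy,
        {f"pair{k:02d}": pair_subtypes[k] for k in range(n_pairs)},
    )
    return matrix, design, truth


def generate(params: SimParams) -> tuple[ProbeMatrix, CohortDesign, SimTruth]:
    """Alias for :func:`simulate_cohort` (single entry point of the module)."""
    return simulate_cohort(params)
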