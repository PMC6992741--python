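"""Synthetic study generator: ground-truth interactions, binding energies,
sequences, and per-tool output tables with controllable operating
characteristics.

The generator emulates the inputs the pipeline consumes in production —
a curated interaction database, duplex energies, transcript sequences and
the tabular outputs of eleven upstream predictors — so the whole system
runs and is testable offline.

Model assumptions:

* Binding energies are a two-component Gaussian mixture: true interactions
  draw from a more stable (more negative) component than negatives. The
  components overlap, as empirical energy distributions do.
* Each tool covers a Bernoulli fraction of pairs; on covered pairs its
  binary call follows its sensitivity (positives) and specificity
  (negatives).
* Continuous payloads (scores, p-values, energies) are drawn from two
  overlapping distributions *conditioned on the emitted call*, never on
  the truth — a tool carries no information beyond its call accuracy, so a
  chance-level tool's features are pure noise by construction.
* Target sequences are i.i.d. nucleotides at a configurable GC fraction;
  one binding site is placed uniformly within each emitted record.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np

from .datasets import InteractionRecord, generate_negatives_by_permutation
from .features import SEED_TYPES, SUPPORTED_TOOLS, ToolRecord

__all__ = [
    "ToolProfile",
    "EnergyModel",
    "SequenceModel",
    "GeneratorConfig",
    "SimulatedStudy",
    "default_tool_profiles",
    "simulate_interactions",
    "simulate_energies",
    "simulate_tool_outputs",
    "simulate_sequences",
    "simulate_study",
]


@dataclass(frozen=True)
class ToolProfile:
    """Operating characteristics of one emulated upstream predictor."""

    sensitivity: float = 0.8
    specificity: float = 0.8
    coverage: float = 0.9
    score_noise: float = 1.0  # scales payload spread around the call means

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.score_noise <= 0:
            raise ValueError("score_noise must be positive")


@dataclass(frozen=True)
class EnergyModel:
    """Two-component Gaussian energy mixture (kcal/mol)."""

    pos_mean: float = -25.0
    pos_sd: float = 3.0
    neg_mean: float = -12.0
    neg_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.pos_sd <= 0 or self.neg_sd <= 0:
            raise ValueError("energy sds must be positive")
        if self.pos_mean >= self.neg_mean:
            raise ValueError("positive component must be more stable (more negative)")


@dataclass(frozen=True)
class SequenceModel:
    target_length: int = 500
    mirna_length: int = 22
    gc: float = 0.5
    site_length: int = 21

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.target_length < self.site_length:
            raise ValueError("target_length must be >= site_length")


def default_tool_profiles() -> dict:
    """Heterogeneous defaults: a few strong sequence/ML tools, several
    conservative low-sensitivity tools, one low-coverage tool."""
    return {
        "RNA22": ToolProfile(0.75, 0.85, 0.90),
        "RNAhybrid": ToolProfile(0.85, 0.80, 0.95),
        "TargetScan": ToolProfile(0.95, 0.90, 0.90),
        "PITA": ToolProfile(0.60, 0.90, 0.80),
        "miRanda": ToolProfile(0.70, 0.85, 0.90),
        "RNAduplex": ToolProfile(0.80, 0.75, 0.95),
        "microT-CDS": ToolProfile(0.65, 0.95, 0.85),
        "STarMirDB": ToolProfile(0.70, 0.80, 0.85),
        "PACCMIT-CDS": ToolProfile(0.55, 0.95, 0.70),
        "MBSTAR": ToolProfile(0.60, 0.90, 0.30),
        "TarPmiR": ToolProfile(0.90, 0.85, 0.90),
    }


@dataclass
class GeneratorConfig:
    n_mirnas: int = 50
    targets_per_mirna: int = 20
    energy: EnergyModel = dc_field(default_factory=EnergyModel)
    sequence: SequenceModel = dc_field(default_factory=SequenceModel)
    tool_profiles: dict = dc_field(default_factory=default_tool_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or self.targets_per_mirna <= 0:
            raise ValueError("counts must be positive")
        for tool in self.tool_profiles:
            if tool not in SUPPORTED_TOOLS:
                raise ValueError(f"unknown tool in profiles: {tool!r}")


@dataclass
class SimulatedStudy:
    """Everything one seeded generator run produces."""

    positives: list  # InteractionRecord, label positive, energy set
    negatives: list  # InteractionRecord, label negative, energy set
    universe: list  # gene ids
    mirna_seqs: dict
    target_seqs: dict
    tool_records: list  # ToolRecord

    @property
    def records(self) -> list:
        return self.positives + self.negatives

    @property
    def truth(self) -> dict:
        return {r.pair: r.label for r in self.records}


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def simulate_interactions(config: GeneratorConfig) -> tuple:
    """Labelled positive/negative pair tables plus the gene universe.

    Each miRNA gets ``targets_per_mirna`` positive targets drawn from a
    universe of ``2 * n_mirnas * targets_per_mirna`` genes; an equal number
    of negatives is drawn by permutation (re-pairing miRNAs with genes
    while excluding positives).
    """
    rng = _rng(config.seed, 1)
    mirnas = [f"mir-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    n_genes = 2 * config.n_mirnas * config.targets_per_mirna
    universe = [f"gene-{i:05d}" for i in range(1, n_genes + 1)]
    positives = []
    for m in mirnas:
        targets = rng.choice(len(universe), size=config.targets_per_mirna, replace=False)
        positives.extend(
            InteractionRecord(m, universe[t], label="positive") for t in sorted(targets)
        )
    neg_pairs = generate_negatives_by_permutation(
        [r.pair for r in positives],
        universe,
        seed=int(rng.integers(2**31)),
        n=len(positives),
    )
    negatives = [InteractionRecord(m, g, label="negative") for m, g in neg_pairs]
    return positives, negatives, universe


def simulate_energies(
    records: Sequence[InteractionRecord], config: GeneratorConfig
) -> list:
    """Attach a Gaussian energy from the record's label component."""
    rng = _rng(config.seed, 2)
    em = config.energy
    out = []
    for r in records:
        if r.label == "positive":
            e = rng.normal(em.pos_mean, em.pos_sd)
        else:
            e = rng.normal(em.neg_mean, em.neg_sd)
        out.append(InteractionRecord(r.mirna_id, r.target_id, r.label, float(e)))
    return out


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_sequences(config: GeneratorConfig, ids: Sequence[str], kind: str = "target") -> dict:
    """Random RNA sequences at the configured GC fraction, keyed by id."""
    rng = _rng(config.seed, 3 if kind == "target" else 4)
    length = (
        config.sequence.target_length if kind == "target" else config.sequence.mirna_length
    )
    return {i: _random_rna(rng, length, config.sequence.gc) for i in ids}


# payload means conditioned on the emitted call: (field, positive-call mean,
# negative-call mean, sd) — overlapping on purpose
_PAYLOADS = {
    "RNA22": [("p_value", 0.02, 0.30, 0.08), ("folding_energy", -22.0, -14.0, 3.0)],
    "RNAhybrid": [("mfe", -24.0, -14.0, 3.0), ("p_value", 0.02, 0.30, 0.08)],
    "TargetScan": [("context_score", -0.45, -0.10, 0.12), ("pct", 0.75, 0.30, 0.15)],
    "PITA": [("ddG", -12.0, -3.0, 3.0), ("dG_duplex", -22.0, -14.0, 3.0), ("dG_open", 8.0, 12.0, 2.5)],
    "miRanda": [("mirsvr_score", -1.0, -0.15, 0.3), ("alignment_score", 160.0, 120.0, 15.0), ("energy", -22.0, -13.0, 3.0)],
    "RNAduplex": [("duplex_energy", -24.0, -14.0, 3.0)],
    "microT-CDS": [("mitg_score", 0.85, 0.40, 0.15)],
    "STarMirDB": [("logistic_probability", 0.8, 0.35, 0.15), ("dG_hybrid", -20.0, -13.0, 3.0), ("dG_nucl", 6.0, 9.0, 2.0), ("dG_total", -14.0, -5.0, 3.0), ("accessibility", 0.6, 0.35, 0.15)],
    "PACCMIT-CDS": [("p_value", 0.03, 0.35, 0.10)],
    "MBSTAR": [("binding_probability", 0.8, 0.35, 0.15)],
    "TarPmiR": [("binding_probability", 0.8, 0.35, 0.15)],
}

_PROB_FIELDS = {
    "p_value",
    "pct",
    "logistic_probability",
    "binding_probability",
    "mitg_score",
    "accessibility",
}

_SITE_TOOLS = {"TargetScan", "miRanda", "RNAduplex", "STarMirDB", "RNAhybrid", "PITA", "MBSTAR"}
_SEED_TOOLS = {"TargetScan", "PITA", "MBSTAR", "STarMirDB"}


def _payload(
    tool: str,
    call_positive: bool,
    profile: ToolProfile,
    rng: np.random.Generator,
    target_len: int,
    site_len: int,
) -> dict:
    fields: dict = {}
    for name, mu_pos, mu_neg, sd in _PAYLOADS[tool]:
        v = rng.normal(mu_pos if call_positive else mu_neg, sd * profile.score_noise)
        if name in _PROB_FIELDS:
            v = float(np.clip(v, 0.0, 1.0))
        fields[name] = float(v)
    if tool in _SITE_TOOLS:
        start = int(rng.integers(1, target_len - site_len + 2))
        fields["site_start"] = start
        fields["site_end"] = start + site_len - 1
    if tool in _SEED_TOOLS:
        if call_positive:
            k = int(rng.integers(1, 3))
            picks = rng.choice(5, size=k, replace=False)  # canonical seed matches
            fields["seed_types"] = ",".join(SEED_TYPES[i] for i in sorted(picks))
        elif rng.random() < 0.7:
            fields["seed_types"] = "seedless"
    if tool == "miRanda":
        if call_positive:
            cat = rng.choice(["S_C", "S_0", "0_C"], p=[0.6, 0.25, 0.15])
        else:
            cat = rng.choice(["0_0", "0_C", "S_0"], p=[0.7, 0.2, 0.1])
        fields["category"] = str(cat)
    if tool == "STarMirDB":
        if call_positive:
            cat = rng.choice(["3US", "CS", "5US"], p=[0.7, 0.2, 0.1])
        else:
            cat = rng.choice(["3ULS", "CLS", "5ULS"], p=[0.6, 0.25, 0.15])
        fields["category"] = str(cat)
    if tool == "TarPmiR":
        fields["me_motif"] = float(rng.random() < (0.7 if call_positive else 0.25))
    return fields


def simulate_tool_outputs(
    records: Sequence[InteractionRecord],
    config: GeneratorConfig,
    profiles: Optional[dict] = None,
) -> list:
    """Per-tool output records for a coverage fraction of pairs.

    On a covered positive pair the tool calls "binding" with probability =
    its sensitivity; on a covered negative pair it calls "non-binding" with
    probability = its specificity. Payload fields are consistent with the
    call (not the truth).
    """
    profiles = config.tool_profiles if profiles is None else profiles
    rng = _rng(config.seed, 5)
    sm = config.sequence
    out: list = []
    for tool in SUPPORTED_TOOLS:
        if tool not in profiles:
            continue
        prof = profiles[tool]
        for r in records:
            if rng.random() > prof.coverage:
                continue
            if r.label == "positive":
                call_positive = rng.random() < prof.sensitivity
            else:
                call_positive = rng.random() >= prof.specificity
            fields = _payload(
                tool, call_positive, prof, rng, sm.target_length, sm.site_length
            )
            fields["call"] = "positive" if call_positive else "negative"
            out.append(ToolRecord(r.mirna_id, r.target_id, tool, fields))
    return out


def simulate_study(config: GeneratorConfig) -> SimulatedStudy:
    """One seeded end-to-end draw: interactions, energies, sequences, tool table."""
    positives, negatives, universe = simulate_interactions(config)
    labelled = simulate_energies(positives + negatives, config)
    positives = [r for r in labelled if r.label == "positive"]
    negatives = [r for r in labelled if r.label == "negative"]
    target_ids = sorted({r.target_id for r in labelled})
    mirna_ids = sorted({r.mirna_id for r in labelled})
    target_seqs = simulate_sequences(config, target_ids, kind="target")
    mirna_seqs = simulate_sequences(config, mirna_ids, kind="mirna")
    tool_records = simulate_tool_outputs(labelled, config)
    return SimulatedStudy(
        positives=positives,
        negatives=negatives,
        universe=universe,
        mirna_seqs=mirna_seqs,
        target_seqs=target_seqs,
        tool_records=tool_records,
    )
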