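"""Encode heterogeneous upstream-tool outputs into one fixed-order feature vector.

Eleven published target-prediction tools are consumed as tabular output
(never re-run here). Their scores, p-values, energies, binding positions,
seed types and categorical calls are mapped onto a single ordered
:class:`FeatureRegistry` spanning six feature categories: binding energy,
scoring function, evolution evidence, binding type, sequence property and
structure. A tool that produced no record for a pair contributes 0 in
every dimension it sources — absence of evidence is encoded as zero, not
as a missing value.

Coordinate convention: binding sites are 1-based inclusive on the target
transcript, 5'->3'. DNA-alphabet input (T) is silently mapped to RNA (U).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "SUPPORTED_TOOLS",
    "SEED_TYPES",
    "RANGE_TOOLS",
    "POSITION_ONLY_TOOLS",
    "SEED_REPORTING_TOOLS",
    "BindingSite",
    "ToolRecord",
    "FeatureDef",
    "FeatureRegistry",
    "FeatureVector",
    "Composition",
    "encode_seed_types",
    "encode_nucleotide_composition",
    "encode_categorical_tool_output",
    "assemble_feature_vector",
    "default_registry",
]

#: The integrated upstream predictors.
SUPPORTED_TOOLS = (
    "RNA22",
    "RNAhybrid",
    "TargetScan",
    "PITA",
    "miRanda",
    "RNAduplex",
    "microT-CDS",
    "STarMirDB",
    "PACCMIT-CDS",
    "MBSTAR",
    "TarPmiR",
)

#: Canonical seed types, in fixed registry order (configurable).
SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer", "CDS-seed", "seedless")

#: Tools whose output carries a start..end binding range, convertible to
#: nucleotide composition of the bound sub-sequence.
RANGE_TOOLS = frozenset({"TargetScan", "miRanda", "RNAduplex", "STarMirDB"})

#: Tools reporting a binding position but no range; position is encoded as a
#: start/length-normalized scalar in [0, 1].
POSITION_ONLY_TOOLS = frozenset({"PITA", "MBSTAR", "RNAhybrid"})

#: Tools whose output contributes to the pooled 7-dimensional seed-type vector.
SEED_REPORTING_TOOLS = frozenset({"TargetScan", "PITA", "MBSTAR", "STarMirDB"})

MIRANDA_CATEGORIES = ("S_C", "S_0", "0_C", "0_0")
STARMIRDB_CATEGORIES = ("3US", "3ULS", "CS", "CLS", "5US", "5ULS")

CATEGORIES = (
    "energy",
    "scoring function",
    "evolution evidence",
    "binding type",
    "sequence property",
    "structure",
)

_RNA_COMPLETION = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U"}


@dataclass(frozen=True)
class BindingSite:
    """1-based inclusive positions of a predicted site on the target."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid binding site {self.start}..{self.end}")

    @classmethod
    def from_zero_based_half_open(cls, start: int, end: int) -> "BindingSite":
        """Convert a 0-based half-open interval to this 1-based inclusive dialect."""
        return cls(start + 1, end)


@dataclass
class ToolRecord:
    """One upstream predictor's raw output for one (miRNA, target) pair.

    ``fields`` maps registry field names to values: floats for scores and
    energies, ints for ``site_start``/``site_end``, a ``seed_types`` set (or
    comma-separated string), a ``category`` label for miRanda/STarMirDB.
    """

    mirna_id: str
    target_id: str
    tool: str
    fields: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tool not in SUPPORTED_TOOLS:
            raise ValueError(
                f"unknown tool {self.tool!r}; supported tools: {', '.join(SUPPORTED_TOOLS)}"
            )

    def site(self) -> Optional[BindingSite]:
        s, e = self.fields.get("site_start"), self.fields.get("site_end")
        if s is None or e is None:
            return None
        return BindingSite(int(s), int(e))


@dataclass(frozen=True)
class Composition:
    """Nucleotide composition of a binding-site sub-sequence."""

    a: float
    c: float
    g: float
    u: float

    @property
    def au(self) -> float:
        return self.a + self.u

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.u, self.au], dtype=float)


#: value kinds a registry entry can take
KINDS = ("continuous", "binary", "onehot")


@dataclass(frozen=True)
class FeatureDef:
    """One registry entry.

    ``tool`` is ``None`` for features pooled across several tools (the
    seed-type vector). For one-hot entries ``group`` names the exclusive
    group and ``member`` the level this dimension indicates. ``source``
    names the encoding rule used by :func:`assemble_feature_vector`.
    """

    name: str
    category: str
    tool: Optional[str]
    kind: str
    source: str
    group: Optional[str] = None
    member: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}")
        if self.tool is not None and self.tool not in SUPPORTED_TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")


class FeatureRegistry:
    """Ordered, category-tagged list of features; the encoding contract.

    The registry fixes the order and meaning of every dimension a
    :class:`FeatureVector` carries. It is a configuration artifact: the
    shipped default covers every feature type the integrated tools emit,
    but custom registries can be loaded from YAML.
    """

    def __init__(self, features: Sequence[FeatureDef], seed_types: Sequence[str] = SEED_TYPES):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        self.features = tuple(features)
        self.seed_types = tuple(seed_types)
        self._index = {f.name: i for i, f in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> tuple:
        return tuple(f.name for f in self.features)

    def index(self, name: str) -> int:
        return self._index[name]

    def tool_of(self, name: str) -> Optional[str]:
        return self.features[self._index[name]].tool

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, handle) -> None:
        doc = {
            "seed_types": list(self.seed_types),
            "features": [
                {
                    k: v
                    for k, v in (
                        ("name", f.name),
                        ("category", f.category),
                        ("tool", f.tool),
                        ("kind", f.kind),
                        ("source", f.source),
                        ("group", f.group),
                        ("member", f.member),
                    )
                    if v is not None
                }
                for f in self.features
            ],
        }
        yaml.safe_dump(doc, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, handle) -> "FeatureRegistry":
        doc = yaml.safe_load(handle)
        feats = [
            FeatureDef(
                name=d["name"],
                category=d["category"],
                tool=d.get("tool"),
                kind=d["kind"],
                source=d["source"],
                group=d.get("group"),
                member=d.get("member"),
            )
            for d in doc["features"]
        ]
        return cls(feats, seed_types=tuple(doc.get("seed_types", SEED_TYPES)))


@dataclass
class FeatureVector:
    """Values aligned to a registry, with an optional training label."""

    values: np.ndarray
    registry: FeatureRegistry
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.registry),):
            raise ValueError(
                f"vector length {self.values.shape} does not match registry size {len(self.registry)}"
            )


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

def encode_seed_types(
    observed: Iterable[str], canon: Sequence[str] = SEED_TYPES
) -> np.ndarray:
    """Indicator vector over the canonical seed types, in canon order."""
    observed = set(observed)
    unknown = observed - set(canon)
    if unknown:
        raise ValueError(
            f"unknown seed type(s) {sorted(unknown)}; accepted names: {list(canon)}"
        )
    return np.array([1.0 if s in observed else 0.0 for s in canon])


def _clean_rna(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch not in _RNA_COMPLETION:
            raise ValueError(f"non-ACGU/T character {ch!r} in sequence")
        out.append(_RNA_COMPLETION[ch])
    return "".join(out)


def encode_nucleotide_composition(
    target_seq: Optional[str], site: Optional[BindingSite]
) -> Composition:
    """Nucleotide fractions (A, C, G, U) of the bound sub-sequence.

    The AU content is the sum of the A and U fractions. An absent site (or
    absent sequence) yields the all-zero composition — the missing-result
    convention, not a uniform prior.
    """
    if site is None or target_seq is None:
        return Composition(0.0, 0.0, 0.0, 0.0)
    seq = _clean_rna(target_seq)
    if site.end > len(seq):
        raise ValueError(
            f"site {site.start}..{site.end} exceeds target length {len(seq)}"
        )
    sub = seq[site.start - 1 : site.end]
    n = len(sub)
    return Composition(
        sub.count("A") / n, sub.count("C") / n, sub.count("G") / n, sub.count("U") / n
    )


def encode_categorical_tool_output(tool: str, label: Optional[str]) -> np.ndarray:
    """One-hot vector over a tool's categorical output levels.

    miRanda classifies each site by mirSVR-score quality x conservation
    (S_C, S_0, 0_C, 0_0); STarMirDB by transcript region x seed usage
    (3US, 3ULS, CS, CLS, 5US, 5ULS). ``label=None`` (no record) gives all
    zeros.
    """
    if tool == "miRanda":
        levels = MIRANDA_CATEGORIES
    elif tool == "STarMirDB":
        levels = STARMIRDB_CATEGORIES
    else:
        raise ValueError(f"tool {tool!r} has no categorical encoding")
    if label is None:
        return np.zeros(len(levels))
    if label not in levels:
        raise ValueError(f"unknown {tool} category {label!r}; accepted: {list(levels)}")
    return np.array([1.0 if lv == label else 0.0 for lv in levels])


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

def _composition_defs(tool: str) -> list:
    return [
        FeatureDef(f"{tool}::comp_{b}", "sequence property", tool, "continuous", "composition", member=b)
        for b in ("a", "c", "g", "u", "au")
    ]


def default_registry(seed_types: Sequence[str] = SEED_TYPES) -> FeatureRegistry:
    """The shipped default registry covering all integrated feature types."""
    F = FeatureDef
    feats: list = []
    # energy
    feats += [
        F("RNAhybrid::mfe", "energy", "RNAhybrid", "continuous", "field"),
        F("RNA22::folding_energy", "energy", "RNA22", "continuous", "field"),
        F("miRanda::energy", "energy", "miRanda", "continuous", "field"),
        F("RNAduplex::duplex_energy", "energy", "RNAduplex", "continuous", "field"),
    ]
    # scoring function
    feats += [
        F("RNAhybrid::p_value", "scoring function", "RNAhybrid", "continuous", "field"),
        F("RNA22::p_value", "scoring function", "RNA22", "continuous", "field"),
        F("TargetScan::context_score", "scoring function", "TargetScan", "continuous", "field"),
        F("miRanda::mirsvr_score", "scoring function", "miRanda", "continuous", "field"),
        F("microT-CDS::mitg_score", "scoring function", "microT-CDS", "continuous", "field"),
        F("STarMirDB::logistic_probability", "scoring function", "STarMirDB", "continuous", "field"),
        F("PACCMIT-CDS::p_value", "scoring function", "PACCMIT-CDS", "continuous", "field"),
        F("MBSTAR::binding_probability", "scoring function", "MBSTAR", "continuous", "field"),
        F("TarPmiR::binding_probability", "scoring function", "TarPmiR", "continuous", "field"),
        F("TarPmiR::me_motif", "scoring function", "TarPmiR", "binary", "field"),
    ]
    # evolution evidence
    feats += [
        F("miRanda::conservation", "evolution evidence", "miRanda", "binary", "field"),
        F("TargetScan::pct", "evolution evidence", "TargetScan", "continuous", "field"),
    ]
    # binding type: positions, categorical calls, pooled seed types
    feats += [
        F("TargetScan::site_start", "binding type", "TargetScan", "continuous", "position"),
        F("TargetScan::site_end", "binding type", "TargetScan", "continuous", "position_end"),
        F("STarMirDB::site_start", "binding type", "STarMirDB", "continuous", "position"),
        F("STarMirDB::site_end", "binding type", "STarMirDB", "continuous", "position_end"),
        F("RNAhybrid::binding_position", "binding type", "RNAhybrid", "continuous", "position"),
        F("PITA::binding_position", "binding type", "PITA", "continuous", "position"),
        F("MBSTAR::binding_position", "binding type", "MBSTAR", "continuous", "position"),
    ]
    feats += [
        F(f"miRanda::cat_{lv}", "binding type", "miRanda", "onehot", "category",
          group="miRanda::category", member=lv)
        for lv in MIRANDA_CATEGORIES
    ]
    feats += [
        F(f"STarMirDB::cat_{lv}", "binding type", "STarMirDB", "onehot", "category",
          group="STarMirDB::category", member=lv)
        for lv in STARMIRDB_CATEGORIES
    ]
    feats += [
        F(f"seed::{st}", "binding type", None, "onehot", "seed_type",
          group="seed", member=st)
        for st in seed_types
    ]
    # sequence property
    feats += [F("miRanda::alignment_score", "sequence property", "miRanda", "continuous", "field")]
    for tool in ("TargetScan", "miRanda", "RNAduplex", "STarMirDB"):
        feats += _composition_defs(tool)
    # structure
    feats += [
        F("PITA::ddG", "structure", "PITA", "continuous", "field"),
        F("PITA::dG_duplex", "structure", "PITA", "continuous", "field"),
        F("PITA::dG_open", "structure", "PITA", "continuous", "field"),
        F("STarMirDB::dG_hybrid", "structure", "STarMirDB", "continuous", "field"),
        F("STarMirDB::dG_nucl", "structure", "STarMirDB", "continuous", "field"),
        F("STarMirDB::dG_total", "structure", "STarMirDB", "continuous", "field"),
        F("STarMirDB::accessibility", "structure", "STarMirDB", "continuous", "field"),
    ]
    return FeatureRegistry(feats, seed_types=seed_types)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

_ENERGY_FIELDS = ("energy", "mfe", "duplex_energy", "folding_energy", "dG_total")


def _most_stable(records: Sequence[ToolRecord]) -> ToolRecord:
    def key(r: ToolRecord) -> float:
        for f in _ENERGY_FIELDS:
            if f in r.fields:
                return float(r.fields[f])
        return float("inf")

    return min(records, key=key)


def _field_name(feature: FeatureDef) -> str:
    return feature.name.split("::", 1)[1]


def assemble_feature_vector(
    pair: tuple,
    records: Sequence[ToolRecord],
    target_seq: Optional[str],
    registry: FeatureRegistry,
    label: Optional[str] = None,
    on_duplicate: str = "error",
) -> FeatureVector:
    """Assemble the fixed-order feature vector for one (miRNA, target) pair.

    Continuous fields are copied verbatim; binding ranges from range-aware
    tools become nucleotide composition; position-only tools contribute a
    length-normalized start position; categorical calls become one-hot
    groups; seed types observed by any seed-reporting tool are pooled into
    the 7-dimensional indicator. Every dimension sourced from a tool with
    no record is 0. The output is a pure function of (records, sequence,
    registry): input record order never matters.

    ``on_duplicate``: ``"error"`` rejects two records from the same tool for
    the pair; ``"most_stable"`` keeps the record with the lowest energy
    field.
    """
    mirna_id, target_id = pair
    by_tool: dict = {}
    for rec in records:
        if (rec.mirna_id, rec.target_id) != (mirna_id, target_id):
            raise ValueError(
                f"record for ({rec.mirna_id}, {rec.target_id}) does not match pair {pair}"
            )
        by_tool.setdefault(rec.tool, []).append(rec)
    chosen: dict = {}
    for tool, recs in by_tool.items():
        if len(recs) > 1:
            if on_duplicate == "most_stable":
                chosen[tool] = _most_stable(recs)
            else:
                raise ValueError(
                    f"duplicate records for pair {pair} from tool {tool}; "
                    "enable the most-stable-energy aggregation rule to allow this"
                )
        else:
            chosen[tool] = recs[0]

    seq = _clean_rna(target_seq) if target_seq is not None else None
    seq_len = len(seq) if seq else None

    # pooled seed types across the seed-reporting tools
    observed_seeds: set = set()
    for tool in SEED_REPORTING_TOOLS:
        rec = chosen.get(tool)
        if rec is None:
            continue
        st = rec.fields.get("seed_types")
        if st is None:
            continue
        if isinstance(st, str):
            st = {s for s in (p.strip() for p in st.split(",")) if s}
        observed_seeds |= set(st)
    seed_vec = encode_seed_types(observed_seeds, registry.seed_types)
    seed_idx = {st: i for i, st in enumerate(registry.seed_types)}

    comp_cache: dict = {}

    def composition_for(tool: str) -> Composition:
        if tool not in comp_cache:
            rec = chosen.get(tool)
            site = rec.site() if rec is not None else None
            comp_cache[tool] = encode_nucleotide_composition(seq, site)
        return comp_cache[tool]

    values = np.zeros(len(registry))
    for i, feat in enumerate(registry):
        rec = chosen.get(feat.tool) if feat.tool is not None else None
        if feat.source == "field":
            if rec is not None:
                values[i] = float(rec.fields.get(_field_name(feat), 0.0))
        elif feat.source in ("position", "position_end"):
            if rec is not None and seq_len:
                site = rec.site()
                if site is not None:
                    pos = site.start if feat.source == "position" else site.end
                    values[i] = min(pos / seq_len, 1.0)
        elif feat.source == "composition":
            comp = composition_for(feat.tool)
            values[i] = getattr(comp, feat.member) if feat.member != "au" else comp.au
        elif feat.source == "category":
            if rec is not None:
                label_val = rec.fields.get("category")
                onehot = encode_categorical_tool_output(feat.tool, label_val)
                levels = MIRANDA_CATEGORIES if feat.tool == "miRanda" else STARMIRDB_CATEGORIES
                values[i] = onehot[levels.index(feat.member)]
        elif feat.source == "seed_type":
            values[i] = seed_vec[seed_idx[feat.member]]
        else:  # pragma: no cover - registry validation guards this
            raise ValueError(f"unknown feature source {feat.source!r}")
    return FeatureVector(values, registry, label=label)
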