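"""Annotated EST catalogue: data model, I/O, classification and composition.

The catalogue is the central container of the pipeline: one row per
assembled contig, with per-library EST counts (the expression
measurements), a functional category, an optional protein family label,
a signal-peptide flag (proxy for secretion into saliva) and optionally
the translated protein sequence.

Functional categories follow the standard sialotranscriptome breakdown:
``housekeeping``, ``secreted``, ``unknown``, ``unknown_secreted``, ``TE``
(transposable elements), ``viral_like`` and ``unassigned``.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "LIFE_STAGES",
    "HOST_CONDITIONS",
    "LibrarySpec",
    "Contig",
    "Catalogue",
    "ClassificationRule",
    "load_rules",
    "default_rules",
    "read_catalogue",
    "write_catalogue",
    "classify",
    "composition",
    "round_half_up",
]

CATEGORIES = frozenset(
    ["housekeeping", "secreted", "unknown", "unknown_secreted", "TE", "viral_like", "unassigned"]
)
LIFE_STAGES = frozenset(["larva", "nymph", "male", "female"])
HOST_CONDITIONS = frozenset(["resistant", "susceptible"])

#: Categories counted by ``scope="secreted_only"`` in :func:`composition`.
SECRETED_SCOPE = frozenset(["secreted", "unknown_secreted"])

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LibrarySpec:
    """One cDNA library: its identifier, biology, and sequencing depth.

    ``total_ests`` is always derived from the count matrix, never trusted
    from metadata, so that corrupted inputs are detected on read.
    """

    library_id: str
    life_stage: Optional[str] = None
    host_condition: Optional[str] = None
    total_ests: int = 0

    def __post_init__(self) -> None:
        if self.life_stage is not None and self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life stage {self.life_stage!r} for library {self.library_id}")
        if self.host_condition is not None and self.host_condition not in HOST_CONDITIONS:
            raise ValueError(
                f"unknown host condition {self.host_condition!r} for library {self.library_id}"
            )
        if self.total_ests < 0:
            raise ValueError("total_ests must be non-negative")


# Library naming convention of 8-library salivary-gland designs:
# stage prefix (UFL/SGN/SGM/SGF) + host-condition suffix (RmS/RmR).
_STAGE_PREFIX = {"UFL": "larva", "SGN": "nymph", "SGM": "male", "SGF": "female"}
_COND_SUFFIX = {"RMS": "susceptible", "RMR": "resistant"}


def _infer_library_spec(library_id: str) -> LibrarySpec:
    stage = next((s for p, s in _STAGE_PREFIX.items() if library_id.upper().startswith(p)), None)
    cond = next((c for s, c in _COND_SUFFIX.items() if library_id.upper().endswith(s)), None)
    return LibrarySpec(library_id=library_id, life_stage=stage, host_condition=cond)


@dataclass
class Contig:
    """One assembled transcript with its per-library EST tallies."""

    contig_id: str
    counts: dict[str, int]
    category: str = "unassigned"
    family: Optional[str] = None
    signal_peptide: bool = False
    description: str = ""
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for contig {self.contig_id}")
        if self.sequence is not None:
            bad = [i for i, aa in enumerate(self.sequence) if aa.upper() not in AA_ALPHABET]
            if bad:
                raise ValueError(
                    f"contig {self.contig_id}: non-amino-acid residue "
                    f"{self.sequence[bad[0]]!r} at position {bad[0] + 1}"
                )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class Catalogue:
    """An annotated EST catalogue: libraries plus contigs.

    Libraries are keyed by ``library_id``; contigs by ``contig_id`` in
    input order. Library totals are recomputed from the contig counts.
    """

    libraries: dict[str, LibrarySpec] = field(default_factory=dict)
    contigs: dict[str, Contig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.recompute_totals()

    def recompute_totals(self) -> None:
        for lib in self.libraries.values():
            lib.total_ests = sum(c.counts.get(lib.library_id, 0) for c in self.contigs.values())

    @property
    def total_ests(self) -> int:
        return sum(lib.total_ests for lib in self.libraries.values())

    def count_matrix(self) -> pd.DataFrame:
        """Contigs x libraries integer count matrix."""
        lib_ids = list(self.libraries)
        data = {
            c.contig_id: [c.counts.get(l, 0) for l in lib_ids] for c in self.contigs.values()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=lib_ids).astype(int)

    def libraries_for(self, host_condition: str) -> list[str]:
        return [l.library_id for l in self.libraries.values() if l.host_condition == host_condition]

    def copy(self) -> "Catalogue":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean ({where})")


def read_catalogue(
    count_table_path,
    annotation_table_path=None,
    fasta_path=None,
    library_specs: Optional[Mapping[str, Mapping]] = None,
) -> Catalogue:
    """Read a catalogue from a TSV count table plus optional annotations/FASTA.

    The count table has ``contig_id`` as its first column and one integer
    column per library. The annotation table carries ``contig_id``,
    ``description``, ``signal_peptide`` and optionally ``category`` and
    ``family``; contigs without annotation default to
    ``category="unassigned"``, ``signal_peptide=False``. FASTA records whose
    id is absent from the count table are dropped with a warning.

    ``library_specs`` optionally maps library ids to ``life_stage`` /
    ``host_condition``; unlisted libraries fall back to the stage-prefix /
    condition-suffix naming convention when it applies.
    """
    counts = pd.read_csv(count_table_path, sep="\t", dtype=str)
    if counts.columns[0] != "contig_id":
        counts = counts.rename(columns={counts.columns[0]: "contig_id"})
    dup = counts["contig_id"][counts["contig_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate contig id {dup.iloc[0]!r} in count table")
    lib_ids = [c for c in counts.columns if c != "contig_id"]

    libraries: dict[str, LibrarySpec] = {}
    for lid in lib_ids:
        meta = (library_specs or {}).get(lid)
        if meta:
            libraries[lid] = LibrarySpec(
                library_id=lid,
                life_stage=meta.get("life_stage"),
                host_condition=meta.get("host_condition"),
            )
        else:
            libraries[lid] = _infer_library_spec(lid)

    annot = pd.DataFrame()
    if annotation_table_path is not None:
        annot = pd.read_csv(annotation_table_path, sep="\t", dtype=str).fillna("")
        annot = annot.set_index("contig_id")

    sequences: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        known = set(counts["contig_id"])
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in known:
                warnings.warn(f"FASTA id {rec.id!r} absent from count table; sequence dropped")
                continue
            sequences[rec.id] = str(rec.seq).upper()

    contigs: dict[str, Contig] = {}
    for _, row in counts.iterrows():
        cid = row["contig_id"]
        cvals: dict[str, int] = {}
        for lid in lib_ids:
            raw = row[lid]
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValueError(f"non-integer count {raw!r} at contig {cid}, library {lid}")
            if v < 0:
                raise ValueError(f"negative count {v} at contig {cid}, library {lid}")
            cvals[lid] = v
        if sum(cvals.values()) == 0:
            raise ValueError(f"empty contig {cid!r}: all library counts are zero")
        kw: dict = {}
        if cid in annot.index:
            arow = annot.loc[cid]
            kw["description"] = str(arow.get("description", ""))
            kw["signal_peptide"] = _parse_bool(
                arow.get("signal_peptide", False), f"contig {cid}, column signal_peptide"
            )
            if str(arow.get("category", "")).strip():
                kw["category"] = str(arow["category"]).strip()
            if str(arow.get("family", "")).strip():
                kw["family"] = str(arow["family"]).strip()
        contigs[cid] = Contig(contig_id=cid, counts=cvals, sequence=sequences.get(cid), **kw)

    return Catalogue(libraries=libraries, contigs=contigs)


def write_catalogue(catalogue: Catalogue, count_table_path, annotation_table_path, fasta_path=None) -> None:
    """Write a catalogue back to the TSV/FASTA dialect :func:`read_catalogue` accepts."""
    mat = catalogue.count_matrix()
    mat.index.name = "contig_id"
    mat.to_csv(count_table_path, sep="\t")

    rows = [
        {
            "contig_id": c.contig_id,
            "description": c.description,
            "signal_peptide": str(c.signal_peptide).lower(),
            "category": c.category,
            "family": c.family or "",
        }
        for c in catalogue.contigs.values()
    ]
    pd.DataFrame(rows).to_csv(annotation_table_path, sep="\t", index=False)

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for c in catalogue.contigs.values():
                if c.sequence:
                    fh.write(f">{c.contig_id}\n{c.sequence}\n")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationRule:
    """Keyword rule: first match wins in an ordered rule list.

    ``contains`` is one or more case-insensitive substrings matched against
    the contig description (any match suffices); ``signal_peptide``, when
    set, additionally requires that flag value.
    """

    category: str
    contains: tuple[str, ...] = ()
    signal_peptide: Optional[bool] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"rule with unknown category name {self.category!r}")
        if isinstance(self.contains, str):
            self.contains = (self.contains,)
        self.contains = tuple(self.contains)

    def matches(self, contig: Contig) -> bool:
        if self.signal_peptide is not None and contig.signal_peptide != self.signal_peptide:
            return False
        desc = contig.description.lower()
        return any(kw.lower() in desc for kw in self.contains) if self.contains else True


def load_rules(path) -> list[ClassificationRule]:
    """Load an ordered rule list from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ClassificationRule(**r) for r in raw]


def default_rules() -> list[ClassificationRule]:
    """The bundled rule set reconstructing the standard secreted-protein families.

    A best-effort keyword reconstruction of a manually curated annotation;
    it reproduces the family vocabulary, not any specific dataset's calls.
    """
    from importlib import resources

    with resources.files("sialomine.data").joinpath("default_rules.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return [ClassificationRule(**r) for r in raw]


def classify(catalogue: Catalogue, rule_set: Sequence[ClassificationRule]) -> Catalogue:
    """Assign a category (and optionally family) to every contig.

    Rules are applied in order, first match wins. Contigs matching no rule
    get ``unknown`` (or ``unknown_secreted`` if flagged with a signal
    peptide). Idempotent for a fixed rule set. Returns a new catalogue.
    """
    out = catalogue.copy()
    for contig in out.contigs.values():
        for rule in rule_set:
            if rule.matches(contig):
                contig.category = rule.category
                if rule.family is not None:
                    contig.family = rule.family
                break
        else:
            contig.category = "unknown_secreted" if contig.signal_peptide else "unknown"
            contig.family = None
    return out


# ---------------------------------------------------------------------------
# Composition summaries
# ---------------------------------------------------------------------------


def composition(
    catalogue: Catalogue,
    group_by: str = "category",
    scope: str = "all",
    grand_total: Optional[int] = None,
) -> pd.DataFrame:
    """Functional composition table: contigs, ESTs, and percent of total.

    Percentages are ``100 * EST count / grand_total`` rounded half-up to 2
    decimals; ``grand_total`` defaults to the catalogue-wide EST total, so
    a scoped table still reports shares of the whole dataset (the printed
    convention for secreted-protein breakdowns). Rows sort by descending
    EST count; family labels are aggregated case-insensitively.
    """
    if group_by not in ("category", "family"):
        raise ValueError("group_by must be 'category' or 'family'")
    if scope not in ("all", "secreted_only"):
        raise ValueError("scope must be 'all' or 'secreted_only'")
    if grand_total is None:
        grand_total = catalogue.total_ests
    if grand_total <= 0:
        raise ValueError("grand_total must be positive")

    contigs: Iterable[Contig] = catalogue.contigs.values()
    if scope == "secreted_only":
        contigs = [c for c in contigs if c.category in SECRETED_SCOPE]

    groups: dict[str, dict] = {}
    for c in contigs:
        if group_by == "category":
            label = c.category
        else:
            label = c.family if c.family else "(no family)"
        key = label.lower()
        g = groups.setdefault(key, {"group": label, "n_contigs": 0, "n_ests": 0})
        g["n_contigs"] += 1
        g["n_ests"] += c.total

    rows = sorted(groups.values(), key=lambda g: (-g["n_ests"], g["group"].lower()))
    df = pd.DataFrame(rows, columns=["group", "n_contigs", "n_ests"])
    df["percent"] = [round_half_up(100.0 * n / grand_total, 2) for n in df["n_ests"]]
    return df
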