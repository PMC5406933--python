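"""Multi-criteria antigen-candidate selection and protein properties.

Candidates for an anti-tick vaccine are salivary proteins that (i) carry a
signal peptide, hence are plausibly injected into the host during feeding
("exposed" antigens); (ii) are upregulated in ticks feeding on susceptible
hosts, i.e. are suppressed by effective anti-tick immunity; and (iii)
belong to a protein family with a putative role in haematophagous
parasitism. Each criterion can be toggled, and per-criterion pass flags
are retained for every contig so the selection is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .catalogue import Catalogue, round_half_up
from .diffexp import DiffExpResult

__all__ = [
    "DEFAULT_FAMILY_WHITELIST",
    "HIS_TAG_KDA",
    "SelectionCriteria",
    "CandidateAntigen",
    "SelectionResult",
    "protein_properties",
    "select_candidates",
]

#: Families with a putative role in haematophagous parasitism
#: (coagulation, immunosuppression, inflammation, attachment).
DEFAULT_FAMILY_WHITELIST = frozenset(
    [
        "metalloproteases",
        "serine protease",
        "calpain",
        "serine carboxypeptidases",
        "kunitz domain",
        "til domain",
        "serpin",
        "thyropin domains",
        "cystatin",
        "carboxypeptidase inhibitor",
        "thrombin inhibitor",
        "cement proteins",
        "glycine rich family",
        "gyy family",
        "ggy family",
        "immunoglobulin binding proteins",
        "lipocalins/histamine binding proteins",
    ]
)

#: Mass added by an N-terminal expression-vector histidine tag, in kDa.
HIS_TAG_KDA = 4.0

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SelectionCriteria:
    require_signal_peptide: bool = True
    require_up_in_susceptible: bool = True
    require_significant: bool = True
    allowed_families: Optional[frozenset[str]] = DEFAULT_FAMILY_WHITELIST
    min_total_ests: int = 0

    def __post_init__(self) -> None:
        if self.allowed_families is not None:
            if self.require_family and not self.allowed_families:
                raise ValueError("allowed_families is enabled but empty")
            self.allowed_families = frozenset(f.lower() for f in self.allowed_families)
        if not any(
            [
                self.require_signal_peptide,
                self.require_up_in_susceptible,
                self.require_significant,
                self.allowed_families is not None,
                self.min_total_ests > 0,
            ]
        ):
            raise ValueError("at least one selection criterion must be enabled")

    @property
    def require_family(self) -> bool:
        return self.allowed_families is not None


@dataclass
class CandidateAntigen:
    contig_id: str
    family: Optional[str]
    diffexp: DiffExpResult
    aa_length: Optional[int]
    mw_kda: Optional[float]
    his_tag_added: bool
    passes: dict[str, bool]
    rank_score: float

    @property
    def selected(self) -> bool:
        return all(self.passes.values())


@dataclass
class SelectionResult:
    """Ranked selected candidates plus the full audit table."""

    candidates: list[CandidateAntigen]
    audit: pd.DataFrame


def protein_properties(sequence: str, his_tag: bool = False) -> tuple[int, float]:
    """Residue count and theoretical molecular weight in kDa (1 decimal).

    Average (not monoisotopic) residue masses plus one water, matching
    SDS-PAGE-scale reporting; an expression-vector histidine tag adds a
    flat 4.0 kDa.
    """
    seq = sequence.upper()
    for i, aa in enumerate(seq):
        if aa not in _STANDARD_AA:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    mw_da = molecular_weight(seq, seq_type="protein", monoisotopic=False) if seq else 18.015
    mw_kda = mw_da / 1000.0 + (HIS_TAG_KDA if his_tag else 0.0)
    return len(seq), round_half_up(mw_kda, 1)


def select_candidates(
    catalogue: Catalogue,
    diffexp_results: Sequence[DiffExpResult],
    criteria: SelectionCriteria = None,
    his_tag: bool = False,
    condition_totals: Optional[tuple[int, int]] = None,
) -> SelectionResult:
    """Apply the selection criteria and rank the surviving candidates.

    Ranking is by descending susceptible/resistant proportion fold-change
    ``(b/N_b) / (a/N_a + 0.5/N_a)`` — the half-count pseudo-proportion keeps
    contigs absent from the resistant libraries finite and top-ranked —
    with ties broken by larger total EST count, then contig id. Every
    catalogue contig appears in the audit table; contigs without a
    differential-expression result (filtered at ``min_count``) fail the
    expression criteria by definition.

    ``condition_totals`` is (resistant depth, susceptible depth); when
    omitted it is derived from the catalogue's library metadata.
    """
    if criteria is None:
        criteria = SelectionCriteria()
    by_id = {r.contig_id: r for r in diffexp_results}
    if condition_totals is None:
        na = sum(
            catalogue.libraries[l].total_ests for l in catalogue.libraries_for("resistant")
        )
        nb = sum(
            catalogue.libraries[l].total_ests for l in catalogue.libraries_for("susceptible")
        )
    else:
        na, nb = condition_totals
    if na <= 0 or nb <= 0:
        raise ValueError(
            "condition depths unavailable: pass condition_totals or annotate libraries "
            "with host_condition"
        )

    audit_rows = []
    candidates = []
    for contig in catalogue.contigs.values():
        dex = by_id.get(contig.contig_id)
        passes: dict[str, bool] = {}
        if criteria.require_signal_peptide:
            passes["signal_peptide"] = contig.signal_peptide
        if criteria.require_up_in_susceptible:
            passes["up_in_susceptible"] = bool(dex and dex.direction == "up_in_susceptible")
        if criteria.require_significant:
            passes["significant"] = bool(dex and dex.significant)
        if criteria.require_family:
            passes["family"] = bool(
                contig.family and contig.family.lower() in criteria.allowed_families
            )
        if criteria.min_total_ests > 0:
            passes["min_total_ests"] = contig.total >= criteria.min_total_ests

        rank_score = 0.0
        if dex is not None:
            rank_score = (dex.observed_b / nb) / (dex.observed_a / na + 0.5 / na)

        aa_length = mw = None
        if contig.sequence:
            aa_length, mw = protein_properties(contig.sequence, his_tag=his_tag)

        cand = CandidateAntigen(
            contig_id=contig.contig_id,
            family=contig.family,
            diffexp=dex,
            aa_length=aa_length,
            mw_kda=mw,
            his_tag_added=his_tag,
            passes=passes,
            rank_score=rank_score,
        )
        audit_rows.append(
            {
                "contig_id": contig.contig_id,
                "family": contig.family or "",
                "total_ests": contig.total,
                **{f"pass_{k}": v for k, v in passes.items()},
                "selected": cand.selected,
                "rank_score": rank_score,
            }
        )
        if cand.selected:
            candidates.append(cand)

    candidates.sort(
        key=lambda c: (
            -c.rank_score,
            -(c.diffexp.observed_a + c.diffexp.observed_b if c.diffexp else 0),
            c.contig_id,
        )
    )
    return SelectionResult(candidates=candidates, audit=pd.DataFrame(audit_rows))
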