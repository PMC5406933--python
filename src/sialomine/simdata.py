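"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes,
at the scale of the motivating study design:

* :func:`simulate_catalogue` — an eight-library salivary-gland EST
  catalogue (larva/nymph/male/female x resistant/susceptible hosts,
  roughly one thousand ESTs per library) with a heavy-tailed baseline
  abundance law, a chosen fraction of contigs differentially expressed
  between host conditions, and descriptions drawn from the standard
  secreted/housekeeping vocabulary;
* :func:`simulate_proteins` — protein sequences with optional
  signal-peptide-like N-termini, glycine-rich repeat blocks, and one
  planted strongly hydrophilic (epitope-like) block whose coordinates
  are recorded as truth;
* :func:`simulate_trial` — a two-group vaccination-trial table with
  overdispersed (negative-binomial) tick counts and Gamma-distributed
  continuous parameters.

All generators are pure functions of (spec, seed); sampling uses a
``numpy`` Generator seeded from the spec, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .catalogue import Catalogue, Contig, LibrarySpec

__all__ = [
    "LibrarySimSpec",
    "CatalogueSimSpec",
    "TrialSimSpec",
    "default_libraries",
    "simulate_catalogue",
    "simulate_proteins",
    "simulate_trial",
    "write_fasta",
]


@dataclass
class LibrarySimSpec:
    library_id: str
    life_stage: str
    host_condition: str
    depth: int


def default_libraries(depth: int = 990) -> list[LibrarySimSpec]:
    """The eight-library design: four life stages x two host conditions.

    The default per-library depth of 990 ESTs makes the catalogue total
    (~7,900) match the scale of a classical Sanger EST survey.
    """
    libs = []
    for prefix, stage in (("UFL", "larva"), ("SGN", "nymph"), ("SGM", "male"), ("SGF", "female")):
        for suffix, cond in (("RmS", "susceptible"), ("RmR", "resistant")):
            libs.append(LibrarySimSpec(f"{prefix}{suffix}", stage, cond, depth))
    return libs


@dataclass
class CatalogueSimSpec:
    """Generative model of an annotated EST catalogue.

    Baseline contig abundances follow a heavy-tailed law (``lognormal``
    with the given sigma, or ``logseries``), mimicking the dominance of a
    few highly expressed salivary transcripts. A ``fraction_differential``
    subset has its susceptible-condition proportion multiplied by
    ``fold_change`` and renormalized, so ``fold_change > 1`` plants
    contigs upregulated in ticks fed on susceptible hosts.
    """

    seed: int
    n_contigs: int = 300
    libraries: list[LibrarySimSpec] = field(default_factory=default_libraries)
    baseline: str = "lognormal"
    baseline_sigma: float = 1.5
    logseries_p: float = 0.995
    fraction_differential: float = 0.1
    fold_change: float = 4.0
    fraction_signal_peptide: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValueError("fraction_differential must be in [0, 1]")
        if not 0.0 <= self.fraction_signal_peptide <= 1.0:
            raise ValueError("fraction_signal_peptide must be in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if any(l.depth < 1 for l in self.libraries):
            raise ValueError("library depths must be >= 1")
        if self.baseline not in ("lognormal", "logseries"):
            raise ValueError("baseline must be 'lognormal' or 'logseries'")


# description vocabulary: (description, family or None, signal peptide)
_SECRETED_VOCAB = [
    ("glycine rich cement protein", "Cement proteins"),
    ("GYY family glycine rich protein", "GYY family"),
    ("Kunitz domain proteinase inhibitor", "Kunitz domain"),
    ("trypsin inhibitor-like TIL domain protein", "TIL domain"),
    ("salivary metalloprotease precursor", "Metalloproteases"),
    ("salivary serine protease", "Serine protease"),
    ("lipocalin histamine binding protein", "Lipocalins/histamine binding proteins"),
    ("immunoglobulin binding protein", "Immunoglobulin binding proteins"),
    ("salivary mucin", "Mucins"),
    ("basic tail secreted protein", "Basic tail family"),
    ("thrombin inhibitor precursor", "Thrombin inhibitor"),
    ("antigen 5 family venom allergen", "Antigen 5 family"),
]
_HOUSEKEEPING_VOCAB = [
    "40S ribosomal protein S3",
    "60S ribosomal protein L10",
    "beta actin",
    "alpha tubulin",
    "cytochrome c oxidase subunit I",
    "heat shock protein 70",
    "elongation factor 1 alpha",
    "ubiquitin conjugating enzyme",
]
_UNKNOWN_VOCAB = ["hypothetical protein", "conserved hypothetical protein"]


def simulate_catalogue(spec: CatalogueSimSpec) -> tuple[Catalogue, pd.DataFrame]:
    """Draw a catalogue and the truth table of planted differential contigs.

    Counts per library are multinomial at the library's target depth (so
    sequencing effort per library is exact), with contig probabilities
    taken from the condition the library belongs to. Contigs that end up
    with zero ESTs in every library are dropped from both the catalogue
    and the truth table (they were never observed). Deterministic given
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_contigs

    if spec.baseline == "lognormal":
        base = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=n)
    else:
        from scipy import stats as _st

        base = _st.logser.rvs(spec.logseries_p, size=n, random_state=rng).astype(float)
    p_resistant = base / base.sum()

    n_diff = int(round(spec.fraction_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    p_susceptible = p_resistant.copy()
    p_susceptible[diff_idx] *= spec.fold_change
    p_susceptible /= p_susceptible.sum()

    min_depth = min(l.depth for l in spec.libraries)
    if (min(p_resistant.min(), p_susceptible.min()) * min_depth) < 0.01:
        warnings.warn("library depths very small for n_contigs: rare contigs expected < 0.01 ESTs")

    probs = {"resistant": p_resistant, "susceptible": p_susceptible}
    counts = {
        l.library_id: rng.multinomial(l.depth, probs[l.host_condition]) for l in spec.libraries
    }

    # annotations: signal-peptide contigs draw from the secreted vocabulary
    signal = rng.random(n) < spec.fraction_signal_peptide
    width = len(str(n))
    contigs: dict[str, Contig] = {}
    truth_rows = []
    direction = "up_in_susceptible" if spec.fold_change > 1 else (
        "up_in_resistant" if spec.fold_change < 1 else "none"
    )
    diff_set = set(diff_idx.tolist())
    for i in range(n):
        cid = f"Rm{i + 1:0{width}d}"
        cvals = {lid: int(counts[lid][i]) for lid in counts}
        if sum(cvals.values()) == 0:
            continue
        if signal[i]:
            desc, family = _SECRETED_VOCAB[rng.integers(len(_SECRETED_VOCAB))]
            category = "secreted"
        elif rng.random() < 0.5:
            desc, family, category = _HOUSEKEEPING_VOCAB[rng.integers(len(_HOUSEKEEPING_VOCAB))], None, "housekeeping"
        else:
            desc, family, category = _UNKNOWN_VOCAB[rng.integers(len(_UNKNOWN_VOCAB))], None, "unknown"
        contigs[cid] = Contig(
            contig_id=cid,
            counts=cvals,
            category=category,
            family=family,
            signal_peptide=bool(signal[i]),
            description=desc,
        )
        if i in diff_set:
            truth_rows.append({"contig_id": cid, "direction": direction,
                               "fold_change": spec.fold_change,
                               "signal_peptide": bool(signal[i]),
                               "family": family or ""})

    libraries = {
        l.library_id: LibrarySpec(l.library_id, l.life_stage, l.host_condition)
        for l in spec.libraries
    }
    catalogue = Catalogue(libraries=libraries, contigs=contigs)
    truth = pd.DataFrame(truth_rows, columns=["contig_id", "direction", "fold_change",
                                              "signal_peptide", "family"])
    return catalogue, truth


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------

# Swiss-Prot-like background amino-acid frequencies.
_BG_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_BG_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_BG_FREQ = _BG_FREQ / _BG_FREQ.sum()

_HYDROPHILIC = list("DENKSQ")   # high Parker propensity
_HYDROPHOBIC = list("LAVIF")    # signal-peptide core


def simulate_proteins(
    n: int,
    length_range: tuple[int, int] = (80, 200),
    planted_epitope: bool = True,
    epitope_len: int = 12,
    glycine_rich: bool = False,
    signal_like: bool = True,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random proteins with optional planted structure, plus truth coordinates.

    Residues are i.i.d. from background frequencies. ``signal_like``
    prepends a signal-peptide-like N-terminus (Met, a charged pair, a
    hydrophobic core). ``glycine_rich`` overwrites an internal block with
    GGX repeats (glycine fraction > 0.5 by construction). The planted
    epitope is a block of strongly hydrophilic residues at a random
    interior position; truth records its 1-based inclusive coordinates.
    """
    lo, hi = length_range
    if lo < 20:
        raise ValueError("minimum protein length is 20")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    rows = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(_BG_AA, size=length, p=_BG_FREQ))
        cursor = 0
        if signal_like:
            core = rng.choice(_HYDROPHOBIC, size=12)
            head = ["M"] + list(rng.choice(list("KR"), size=2)) + list(core) + ["A"]
            seq[: len(head)] = head
            cursor = len(head)
        gly_start = gly_end = 0
        if glycine_rich:
            rep = int(rng.integers(4, 8))  # number of GGX triplets
            block = []
            for _ in range(rep):
                block += ["G", "G", str(rng.choice(list("YSL")))]
            start = int(rng.integers(cursor, max(cursor + 1, length - len(block) - epitope_len - 1)))
            seq[start : start + len(block)] = block
            gly_start, gly_end = start + 1, start + len(block)
        ep_start = ep_end = 0
        if planted_epitope:
            # interior position clear of the N-terminal signal region
            lo_pos = max(cursor, gly_end)
            start = int(rng.integers(lo_pos, length - epitope_len))
            block = rng.choice(_HYDROPHILIC, size=epitope_len)
            seq[start : start + epitope_len] = list(block)
            ep_start, ep_end = start + 1, start + epitope_len
        sid = f"prot{k + 1:03d}"
        seqs[sid] = "".join(seq[:length])
        rows.append({"sequence_id": sid, "length": length,
                     "epitope_start": ep_start, "epitope_end": ep_end,
                     "gly_start": gly_start, "gly_end": gly_end})
    return seqs, pd.DataFrame(rows)


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Trial
# ---------------------------------------------------------------------------


@dataclass
class TrialSimSpec:
    """Generative model of a two-group tick-challenge trial.

    Defaults reproduce the scale of a small cattle trial: 4 vaccinated vs
    3 control animals, control means of 1,233 engorged females of 338 mg,
    107.5 mg of eggs per tick and 0.022 g larvae per g eggs. The default
    coefficients of variation are moderate values typical of controlled
    challenge infestations (count burdens more variable than the
    reproductive indices); published standard errors from trials this
    small are too noisy to anchor dispersion defaults. Vaccinated group
    means are the control means times the per-parameter multipliers.
    """

    seed: int
    n_vaccinated: int = 4
    n_control: int = 3
    control_means: dict = field(
        default_factory=lambda: {
            "n_ticks": 1233.0,
            "tick_weight_mg": 338.0,
            "egg_mass_mg_per_tick": 107.5,
            "larvae_g_per_g_eggs": 0.022,
        }
    )
    cv: dict = field(
        default_factory=lambda: {
            "n_ticks": 0.3,
            "tick_weight_mg": 0.15,
            "egg_mass_mg_per_tick": 0.15,
            "larvae_g_per_g_eggs": 0.2,
        }
    )
    multipliers: dict = field(
        default_factory=lambda: {
            "n_ticks": 0.476,
            "tick_weight_mg": 0.447,
            "egg_mass_mg_per_tick": 0.819,
            "larvae_g_per_g_eggs": 0.727,
        }
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.control_means.values()):
            raise ValueError("control means must be positive")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("CVs must be non-negative")


def _draw_counts(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Negative-binomial counts matched to (mean, CV); Poisson if underdispersed."""
    var = (mean * cv) ** 2
    if var <= mean:
        return rng.poisson(mean, size=size)
    r = mean**2 / (var - mean)
    return rng.negative_binomial(r, r / (r + mean), size=size)


def _draw_gamma(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def simulate_trial(spec: TrialSimSpec) -> pd.DataFrame:
    """Draw a per-animal trial table; deterministic given the spec's seed.

    Tick counts are negative-binomial (overdispersed parasite burdens);
    the continuous parameters are Gamma with matched mean and CV.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group, ngrp in (("vaccinated", spec.n_vaccinated), ("control", spec.n_control)):
        mult = spec.multipliers if group == "vaccinated" else {}
        draws = {}
        for p, m in spec.control_means.items():
            mean = m * mult.get(p, 1.0)
            if p == "n_ticks":
                draws[p] = _draw_counts(rng, mean, spec.cv[p], ngrp)
            else:
                draws[p] = _draw_gamma(rng, mean, spec.cv[p], ngrp)
        tag = "V" if group == "vaccinated" else "C"
        for i in range(ngrp):
            rows.append(
                {
                    "animal_id": f"{tag}{i + 1}",
                    "group": group,
                    **{p: float(draws[p][i]) if p != "n_ticks" else int(draws[p][i])
                       for p in spec.control_means},
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)
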