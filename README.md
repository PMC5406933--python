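# sialomine

Host-immunity-guided antigen discovery from tick salivary-gland EST
catalogues, with the vaccine-trial statistics used to evaluate the
resulting antigens.

## The problem

The cattle tick *Rhipicephalus microplus* completes its whole parasitic
cycle on one host, and its salivary proteins — injected during feeding —
mediate attachment, anticoagulation and immunosuppression. Hosts differ
genetically in anti-tick immunity: ticks feed well on susceptible breeds
(*Bos taurus taurus*) and poorly on resistant ones (*B. t. indicus*).
Salivary transcripts that a tick expresses strongly on susceptible hosts
but weakly on resistant ones are therefore candidate targets of effective
host immunity, and good candidates for an anti-tick vaccine based on
"exposed" antigens that natural infestations can boost.

`sialomine` implements that reverse-vaccinology pipeline for digital
(EST-count) expression data:

1. **catalogue** — an annotated EST catalogue (contigs × libraries count
   matrix plus functional annotations), keyword-rule classification into
   the standard sialotranscriptome categories, and composition tables
   (percent of total ESTs per category or protein family);
2. **diffexp** — chi-square contrasts of per-contig EST counts between
   host conditions against depth-proportional expected counts
   `E_i = T · N_i / (N_a + N_b)`, as a goodness-of-fit or a 2×2
   contingency statistic, with upper-tail p-values;
3. **antigens** — multi-criteria candidate selection (signal peptide,
   upregulation on susceptible hosts, statistical significance, family
   whitelist), fold-change ranking with a full audit table, and
   theoretical protein molecular weights (average residue masses,
   optional +4 kDa histidine tag);
4. **epitopes** — linear B-cell epitope scanning by a centered
   Parker-hydrophilicity window, and generic MHC-II scanning of 9-mers
   against user-supplied position-specific scoring matrices;
5. **efficacy** — trial summaries, percent reductions, Student/Welch t
   comparisons, and the multiplicative efficacy statistic
   `E = 100 × [1 − (CRT × CRO × CRF)]` from the vaccinated/control
   ratios of tick number (NT), oviposition (O) and egg fertility (F);
6. **simdata** — seeded generators for every stage: multinomial EST
   catalogues with planted fold-changes, proteins with planted
   hydrophilic epitope blocks, and two-group trial tables.

## Worked example

The efficacy statistic from the published group means of a 4-vs-3 calf
trial (counts of engorged adult females, egg-mass weight per surviving
tick in mg, larvae weight per gram of eggs):

```python
from sialomine import compute_efficacy

res = compute_efficacy({
    "vaccinated": {"n_ticks": 587,  "egg_mass_mg_per_tick": 88.0,  "larvae_g_per_g_eggs": 0.016},
    "control":    {"n_ticks": 1233, "egg_mass_mg_per_tick": 107.5, "larvae_g_per_g_eggs": 0.022},
})
print(f"CRT={res.crt:.3f} CRO={res.cro:.3f} CRF={res.crf:.3f}  E={res.e_percent:.1f}%")
```

prints

```
CRT=0.476 CRO=0.819 CRF=0.727  E=71.7%
```

i.e. vaccination left 47.6% of the tick burden, 81.9% of the oviposition
and 72.7% of the egg fertility, for an overall efficacy that rounds to
**72%**: vaccinated animals supported 28% of the control group's tick
reproductive output.

The discovery side runs the same way from the shell, here on synthetic
data:

```
$ sialomine simulate catalogue --seed 11 --out cat
$ sialomine diffexp --counts cat/counts.tsv --annot cat/annotations.tsv --out diffexp.tsv
204 contigs tested, 46 significant at alpha=0.05
$ sialomine select --counts cat/counts.tsv --annot cat/annotations.tsv \
      --out candidates.tsv --audit audit.tsv
4 candidates selected -> candidates.tsv
```

The simulated catalogue planted 10% of contigs at fold-change 4 between
host conditions; the 46 flagged contigs are dominated by those, and the
four ranked candidates are the flagged contigs that additionally carry a
signal peptide and a whitelisted parasitism-related family — the same
funnel that yields priority antigens on a real catalogue.

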