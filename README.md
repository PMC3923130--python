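# mirevol

Analytics for microRNA evolution across development: how a microRNA's
evolutionary **age** and sequence **divergence** relate to **when** in
development it is expressed.

MicroRNA repertoires grow continuously: some families predate the
Bilateria, others arose within a single genus. Between two congeneric
species (a reference such as *D. virilis* and a partner such as
*D. melanogaster*), old families accumulate fewer substitutions than young
ones, and fast-evolving microRNAs tend to be expressed early in
embryogenesis while conserved ones dominate later stages. `mirevol`
implements the full analysis chain behind such observations, plus a
phylogeny-aware synthetic-data generator with known ground truth so every
step can be validated end to end. It is aimed at small-RNA / molecular
evolution researchers who want these statistics as tested, scriptable
building blocks rather than one-off notebook code.

## What it computes

* **Ortholog pairing** — reciprocal best hits under deterministic global
  alignment (match +2 / mismatch −3, affine gaps), with optional synteny
  support from flanking-gene tables. Ties are rejected: accepted pairs are
  unambiguous 1-to-1 orthologs.
* **Parsimony ages** — on a rooted species tree whose nodes carry age
  ranks 1..7 (1 = youngest clade, 7 = Bilateria), a family's origin is the
  MRCA of all species carrying a homolog; families inherit the age of
  their oldest paralog.
* **Region-partitioned divergence** — substitutions per site and the
  Kimura two-parameter distance
  `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`
  over the whole hairpin, the mature arm(s), the 6-mer seed (arm positions
  2–7), and the loop/stem extension; integer mature substitution counts
  classed 0 / 1–2 / ≥3.
* **Expression processing** — small-RNA read filtering (19–24 nt, <5
  genomic loci, ≤1 mismatch), hairpin counting, equal splitting of reads
  shared by identical-mature paralogs, RPM normalization against microRNA-
  or genome-mapped totals, expression breadth, and outlier flagging.
* **Stage analytics** — divergence-tertile expression composition per
  stage, per-stage Spearman ρ(divergence, expression), breadth contrasts
  (Welch's t), and the transcriptome age / divergence indices

      TAI_s = Σ a_i e_is / Σ e_is      TDI_s = Σ n_i e_is / Σ e_is

  with bootstrap standard deviations (B = 1000, microRNAs resampled).

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Run the whole pipeline on a synthetic study (300 microRNA families, 11
developmental libraries) and inspect the stage profile:

```bash
mirevol run-all -o run1    # defaults; add -c config.yaml to override
```

```python
import pandas as pd
prof = pd.read_csv("run1/analyze/stage_indices.tsv", sep="\t", index_col=0)
print(prof[["tai", "tdi", "tdi_sd", "rho"]].round(4))
```

```
          tai     tdi  tdi_sd     rho
stage
e0     4.2377  0.1037  0.0072 -0.2783
e2     4.7307  0.0934  0.0054 -0.3151
e4     5.0916  0.0835  0.0061 -0.4742
e6     5.4314  0.0742  0.0047 -0.5827
e8     5.4992  0.0675  0.0050 -0.6098
e10    5.8496  0.0647  0.0048 -0.6764
e12    6.0059  0.0565  0.0049 -0.7296
e14    6.0930  0.0552  0.0041 -0.7500
e16    6.3166  0.0470  0.0041 -0.8055
larva  6.4837  0.0453  0.0050 -0.7941
adult  6.4578  0.0441  0.0045 -0.8034
```

(Output for `seed: 1`.) Reading the table: the earliest embryonic library
has the *youngest* (lowest TAI) and *fastest-evolving* (highest TDI)
microRNA transcriptome; both indices move monotonically toward old,
conserved profiles by the adult stage, and the divergence–expression
correlation ρ strengthens from −0.28 at e0 to −0.80 in the adult — the
early embryo is where fast-evolving microRNAs contribute most.
`run1/analyze/composition.tsv` holds the matching divergence-tertile
shares (the fast tertile falls from ~25% of expression at e0 to ~1% in the
adult), and `run1/manifest.json` records config, seeds, and SHA-256
digests of every table for reproducibility.

Each stage is also available separately (`mirevol simulate | homology |
divergence | expression | analyze | validate`), and everything is callable
as a library (`mirevol.kimura2p`, `mirevol.assign_age`,
`mirevol.stage_index_profile`, …).

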