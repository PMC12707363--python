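# splicescout

Sequence-based pre-selection of split inteins by aggregation propensity,
with protein trans-splicing (PTS) kinetics fitting and SEC molecular-weight
calibration.

## The problem

Split inteins ligate two separately expressed protein halves with a native
peptide bond (protein trans-splicing), which makes them workhorses for
protein semisynthesis, segmental labelling and cysteine-free bioconjugation.
Many candidates fail in practice, though: before association with its Int^C
partner, the Int^N fragment is only partially folded — a molten-globule-like
N-terminal lobe (**N1**) followed by a disordered, highly charged C-terminal
lobe (**N2**) — and β-sheet-driven aggregation seeded in the N2 lobe
sequesters the precursor into splicing-inactive assemblies.

`splicescout` screens candidates *before* any wet-lab work. For an Int^N
sequence it computes a per-residue amyloidogenicity consensus, splits the
fragment into its N1/N2 lobes, and scores each lobe. The predictive metric is
the ratio

    r = s_N2 / s_N1

of the per-residue aggregation scores of the two lobes: **r < 1** predicts an
efficient splicer, **r > 1** an aggregation-prone candidate. The package also
fits PTS splice-product time courses to the pseudo-first-order one-phase
exponential SP(t) = SP_max·(1 − e^(−kt)) (rate k, half-life ln 2/k,
efficiency SP_max/P_N0) and performs linear SEC calibrations (log MW or MW
vs. retention time) for judging aggregate content.

## What is inside

| module | contents |
|---|---|
| `splicescout.records` | FASTA I/O, `InteinRecord` (catalytic 1/+1 residues, cysteine-less classification, Cys→Ser variants), motif annotation (blocks A/B/F/G, NX) |
| `splicescout.predictors` | per-residue tracks: AGGRESCAN a3v window scale, amyloidogenic hexapeptide pattern, mean packing density, Chou–Fasman β propensity; majority consensus |
| `splicescout.lobes` | N1/N2 boundary transfer by global alignment from an annotated reference, lobe scores, N2/N1 ratio classification |
| `splicescout.panel` | Spearman ρ (t-approximation or exact/Monte-Carlo permutation p), OLS fits, cross-intein panel report |
| `splicescout.kinetics` | one-phase exponential fitting with analytic gradient, half-lives, splicing efficiency, SEC calibration |
| `splicescout.synthetic` | seeded generators for intein-like sequences, splice time courses and score-coupled panels with known ground truth |

## Worked example

```python
import splicescout as ss

# score two synthetic Int^N fragments: one clean, one with amyloid load in N2
for tag, n2_inserts in (("clean", 0), ("n2-loaded", 3)):
    spec = ss.SyntheticInteinSpec(seed=42, n_amyloid_inserts_n2=n2_inserts)
    rec, part, _ = ss.make_intein(spec)
    sc = ss.lobe_scores(ss.score_sequence(rec.intN), part)
    print(f"{tag:10s} s_N1={sc.s_n1:.3f} s_N2={sc.s_n2:.3f} "
          f"s_total={sc.s_total:.3f} ratio={sc.ratio:.2f} -> {sc.classification}")

tc = ss.make_timecourse(k=1.3e-3, sp_max=9.5, sigma=0.2, n_points=12,
                        t_max=4000.0, seed=7, pn0=10.0)
fit = ss.fit_one_phase(tc)
print(f"k = {fit.k*1e3:.2f}e-3 1/s, t_1/2 = {fit.t_half/60:.1f} min, "
      f"efficiency = {fit.efficiency:.0%}")
```

prints

```
clean      s_N1=0.167 s_N2=0.000 s_total=0.083 ratio=0.00 -> efficient_predicted
n2-loaded  s_N1=0.167 s_N2=0.283 s_total=0.225 ratio=1.70 -> aggregation_prone_predicted
k = 1.27e-3 1/s, t_1/2 = 9.1 min, efficiency = 96%
```

The two Int^N fragments share the same N1 lobe (s_N1 = 0.167, the fraction
of N1 residues flagged by the 4-method consensus). Seeding three
amyloidogenic hexapeptides into the disordered N2 lobe raises its score to
0.283, pushing the N2/N1 ratio to 1.70 — above the cutoff of 1, so the
fragment is flagged as aggregation-prone. The kinetics fit recovers the
generating parameters of the noisy trace (true k = 1.30 × 10⁻³ s⁻¹,
efficiency 95%) within the noise.

The same pipeline is available from a shell:

```bash
splicescout score --fasta intN.fa --out tracks.tsv
splicescout classify --fasta intN.fa --reference ref.json --out scores.tsv
splicescout panel --scores scores.tsv --out panel.json
splicescout fit-kinetics --csv timecourse.csv --pn0 10
splicescout sec --csv standards.csv --void-time 3.5 --predict 3.5
splicescout simulate intein --seed 1 --n2-inserts 3 --out syn.fa
```

Absolute consensus scores depend on the method set (four local predictors
here, versus web consensus servers with larger method panels), so analyses
should rely on rank order and classification, which are stable across
consensus choices — see `docs/methods.md`.

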