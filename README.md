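# nhejoin

Reconstruction and mechanistic classification of NHEJ-mediated
chromosomal translocation junctions, with a matched mechanism simulator
and the cohort statistics of intron-based yeast translocation assays.

## The problem

When two simultaneous double-strand breaks on different chromosomes are
induced by staggered endonuclease cuts (HO and I-SceI, each leaving a
4-nt 3'-protruding overhang), classical non-homologous end-joining can
join the wrong ends and produce a reciprocal translocation. In the
intron-based assay family this package models, each surviving
translocant yields one sequenced junction, and the repair event behind
it — how much of each end was trimmed, what annealed to what, which gaps
were filled by templated synthesis — must be inferred from the sequence
alone and assigned to a mechanistic class:

* **partially complementary ends** — Type I (gap-filling across 1–2-nt
  terminal pairing, the `+CA/+AT` signature), Type II (≥4-nt
  microhomology with deletion), Type III (direct ligation after terminal
  trimming, tolerating one T:G mismatch), Type IV (end-bridging from a
  blunted end across the intact overhang);
* **non-complementary ends** — Type I (two-strand gap-filling), Type II
  (microhomology + one-strand fill), Type III (microhomology, no fill).

The package is for researchers analysing end-joining junction sequences
(or building simulations of them): it gives an exhaustive, reproducible
version of the by-inspection analysis such studies report.

## How it works

For an observed junction `J` and the two configured ends, every repair
event satisfying

    J == left_top[:len−t₁] + insertion + right_top[t₂:]

within the assay bounds is enumerated (one tolerated mismatch inside an
annealed pairing region may resolve to either strand's allele), annotated
with pairing length, microhomology, and templated-fill flags, and ranked
by parsimony: fewest edited nucleotides, then maximal microhomology,
fewest mismatches, templated before untemplated, left-aligned ties. The
winner is classified by a deterministic decision tree per assay system.
A simulator executes each mechanism literally on the same configured
ends, so the whole pipeline is testable without the original sequencing
data; cohort statistics (frequencies from plating counts, medians,
Mann-Whitney, chi-square on type distributions, translocated-chromosome
size arithmetic) round out the analysis. See `docs/methods.md` for the
full model.

## Worked example

```python
from nhejoin import builtin_assay, Junction, classify_junction, classify_cohort
from nhejoin.simulate import default_profile, simulate_cohort
from nhejoin.io import render_summary_text

assay = builtin_assay("partial")

# a junction carrying the canonical gap-filling signature
top = assay.left_top + "CA" + assay.right_top
cj = classify_junction(Junction(id="colony-07", top=top, assay=assay))
e = cj.explanation
print(f"{cj.junction_id}: Type {cj.repair_type.label} ({cj.repair_type.description})")
print(f"  pairing={e.pairing_len} nt, insertion={e.insertion_top!r} "
      f"(templated_top={e.templated_top}), trims L/R = "
      f"{e.trim_left_prot}/{e.trim_right_prot}, mismatches={e.mismatches_in_pairing}")

# a simulated wild-type cohort, classified back
profile = default_profile("partial", "WT")
cohort = simulate_cohort(profile, 24, assay, seed=7)
dist = classify_cohort([sj.junction for sj in cohort])
print(render_summary_text([("WT (simulated)", dist)]))
```

prints

```
colony-07: Type I (Gap-filling-mediated)
  pairing=2 nt, insertion='CA' (templated_top=True), trims L/R = 0/0, mismatches=0
strain          n   Type I    Type II  Type III  Type IV  unclassifiable  ambiguous
WT (simulated)  24  67% (16)  21% (5)  8% (2)    4% (1)   0               0
```

The first block reads: both overhangs intact, 2-nt terminal pairing, the
2-nt gap filled with `CA` templated by the opposing overhang — the
diagnostic Type I event. The cohort table has the shape of the published
per-genotype tables: counts are ground truth, percentages are rendered
from them by integer rounding.

The same pipeline is scriptable from the shell:

```
nhejoin simulate --assay partial --strain WT --n 24 --seed 7 --out-prefix out/wt
nhejoin classify out/wt.fasta --assay partial --out-prefix out/wt
nhejoin tables --seed 0 --out-dir out/tables     # all default genotypes, both systems
```

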