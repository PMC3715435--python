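# Non-complementary translocation assay (HO x inverted I-SceI).
#
# Inverting the I-SceI site flips its cleavage window, so the upstream
# (left) fragment now carries the 4-nt 3' overhang TTAT; the right end is
# the same HO fragment as in the partial assay (bottom-strand overhang
# TGTT).  TTAT and TGTT share no perfect terminal pairing register — the
# ends are completely non-complementary, which is what defines this
# system.
#
# Flanks are SYNTHETIC stand-ins (the original intron context is
# image-only): the left flank carries one full annealing site for the
# right overhang (AACA ending 14 nt in from the left 3' terminus) and the
# right flank carries suffix microhomologies of the left overhang (TAT/AT
# 5-6 nt in).

name = noncomp

left.flank_top = GTATGTTCTTCAGATCGGTAGCTTCGAACATCGGTCTTCG
left.overhang = TTAT

right.overhang_bottom = TGTT
right.flank_top = CGGTCTATAACCTGGACGGCTTCAGGCTGGTCGCAGGTCC

left_anchor = GTATGTTCTT
right_anchor = TCGCAGGTCC

overhang_length = 4
max_deletion = 25
max_insertion = 6

# Only the product sizes (1450 and 730 kb) are published; lengths and
# break offsets are a synthetic reconstruction consistent with them.
# Chromosomes VII and XV co-migrate (~1090 kb) on the gels.
karyotype.chrom.VII = 1090,964
karyotype.chrom.XV = 1090,604
karyotype.product.tVII/XV = VII,XV
karyotype.product.tXV/VII = XV,VII
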