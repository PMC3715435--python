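# Partially-complementary translocation assay (HO x I-SceI).
#
# Overhangs are reconstructed from the canonical enzyme cut-site geometries:
# the left end is the upstream fragment of an I-SceI cut (4-nt 3' overhang
# ATAA on the top strand), the right end the downstream fragment of an HO
# cut (4-nt 3' overhang TGTT on the bottom strand, i.e. the reverse
# complement of the HO overhang AACA).  At the 2-nt terminal pairing
# register these ends leave 2-nt gaps whose templated fill is +CA (top) /
# +AT (bottom), and after single-nucleotide trimming the 3-nt pairing
# carries one T:G mismatch — the diagnostic signatures of this assay.
#
# The published assay embeds the ends in the ACT1 intron of a split LEU2
# reporter; that intron context is available only as figure images, so the
# flanks below are SYNTHETIC stand-ins (unverified against the original
# text) constructed to carry one >=4-nt microhomology site for each
# overhang within the deletion window: AACA (the pairing image of the
# right overhang) ends 14 nt from the left end's 3' terminus, and ATAA
# (the left overhang) lies 6 nt into the right flank.

name = partial

left.flank_top = GTATGTTCTTCAGATCGGTAGCTTCGAACATCGGTCTTCG
left.overhang = ATAA

right.overhang_bottom = TGTT
right.flank_top = CGGTCTATAACCTGGACGGCTTCAGGCTGGTCGCAGGTCC

left_anchor = GTATGTTCTT
right_anchor = TCGCAGGTCC

overhang_length = 4
max_deletion = 25
max_insertion = 6

# Parental chromosome sizes and break positions (kb).  Only the product
# sizes (596 and 811 kb) are published; lengths and break offsets are a
# synthetic reconstruction consistent with them.
karyotype.chrom.III = 317,110
karyotype.chrom.XV = 1090,604
karyotype.product.tIII/XV = III,XV
karyotype.product.tXV/III = XV,III
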