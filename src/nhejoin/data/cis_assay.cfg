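# In-cis deletion assay: two inverted I-SceI sites flanking a counter-
# selectable marker on one chromosome.  Joining the two distal ends
# deletes the marker; survivors are scored as 5-FOA-resistant colonies and
# the repair frequency uses the same plating arithmetic as the
# translocation assays.
#
# Both ends are I-SceI products: the left (upstream) fragment carries the
# 3' overhang ATAA on the top strand; the inverted downstream site leaves
# the right fragment with the bottom-strand overhang ATAA.  The two
# overhangs share no perfect terminal pairing register (non-complementary
# system).  Flanks are SYNTHETIC stand-ins.

name = cis

left.flank_top = GTATGTTCTTCAGATCGGTAGCTTCGTTATCGGTCTTCG
left.overhang = ATAA

right.overhang_bottom = ATAA
right.flank_top = CGGTCTAACCTGGACGGCTTCAGGCTGGTCGCAGGTCC

left_anchor = GTATGTTCTT
right_anchor = TCGCAGGTCC

overhang_length = 4
max_deletion = 25
max_insertion = 6
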