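# Raw annotation consequence terms (VEP and ANNOVAR dialects) mapped onto the
# closed class set {missense, frameshift_indel, stopgain, splice, other}.
# Terms are matched case-insensitively; anything absent maps to "other".

# VEP
missense_variant: missense
frameshift_variant: frameshift_indel
stop_gained: stopgain
splice_acceptor_variant: splice
splice_donor_variant: splice
splice_region_variant: splice
synonymous_variant: other
stop_lost: other
start_lost: other
inframe_insertion: other
inframe_deletion: other
intron_variant: other
5_prime_UTR_variant: other
3_prime_UTR_variant: other

# ANNOVAR
nonsynonymous SNV: missense
frameshift insertion: frameshift_indel
frameshift deletion: frameshift_indel
stopgain: stopgain
stoploss: other
splicing: splice
synonymous SNV: other
nonframeshift insertion: other
nonframeshift deletion: other

# short/internal labels
missense: missense
frameshift_indel: frameshift_indel
splice: splice
other: other
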