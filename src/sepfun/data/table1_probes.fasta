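>probe_sense_T rs4957796 risk allele T at offset 16 (0-based)
CAAAATTTATAAATATTACATCATTGAAATTAT
>probe_antisense_T reverse complement of probe_sense_T
ATAATTTCAATGATGTAATATTTATAAATTTTG
>probe_sense_C rs4957796 alternative allele C at offset 16 (0-based)
CAAAATTTATAAATATCACATCATTGAAATTAT
>probe_antisense_C reverse complement of probe_sense_C
ATAATTTCAATGATGTGATATTTATAAATTTTG
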