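# Expressed PPR genes showing nucleotide conversion (10 of 465 expressed)
AT3G62470
AT1G50270
AT1G16830
AT1G63080
AT1G06580
AT3G56550
AT1G09820
AT3G53360
AT2G22410
AT4G32430
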