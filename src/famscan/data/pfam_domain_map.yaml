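# Pfam accession -> internal domain token used for topology classification.
# PF00005 (ABC transporter NBD) and PF01061 (ABC-2 family) both carry the
# nucleotide-binding fold; PF00664 is the transporter transmembrane region.
# Users may override this file via the accession_map argument / --config.
PF00005: NBD
PF01061: NBD
PF00664: TMD
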