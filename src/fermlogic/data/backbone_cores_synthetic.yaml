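# Synthetic sigma70-style core promoter sequences (-35..-1, 35 bp each).
#
# These are SYNTHETIC stand-ins built around the sigma70 consensus hexamers
# (TTGACA at offset 0, TATAAT at offset 23, 17 bp spacer), not the registry
# sequences of any named constitutive promoter.  Each core was screened to
# be free of duplicated 6-mers, BsaI sites, and stray near-consensus
# hexamers, so the default library's filter failures all come from operator
# insertion.  Replace them with real registry/literature core sequences via
# a custom DesignSpec to reproduce a specific published backbone; note that
# cores containing internal >=6 bp direct repeats (e.g. cloning-scar
# flanked promoters) will fail the default repeat screen unless
# min_repeat_len is raised.
cores:
  synA: TTGACAGGAAATTCGTGGGTTACTATAATCTCCAT
  synB: TTTACAACCTCCTCCAGTGACCTTATTATGACGAC
  synC: TTGACTGAGTGGTAAACGCAGTGTACAATGGTCGG
  synD: CTGACAACCTATAGCGTGAGCGGTATACTCTGGCG
minus35_offset: 0
minus10_offset: 23
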