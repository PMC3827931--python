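# name: rna_hbond
# source: PROVISIONAL defaults. Intended semantics: per-base hydrogen-bonding
# source: contact propensity at RNA-protein interfaces derived from contact
# source: statistics over a set of solved complexes. The original numeric
# source: tables are not published; replace this file with values recomputed
# source: from interface contact counts for exact reproduction. Defaults
# source: reflect the relative hydrogen-bonding capacity of each base edge
# source: (guanine-rich contacts most frequent).
# alphabet: rna
A	0.80
C	1.00
G	1.25
U	1.10
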