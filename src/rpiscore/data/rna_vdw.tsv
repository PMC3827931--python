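# name: rna_vdw
# source: PROVISIONAL defaults. Intended semantics: per-base van der Waals
# source: contact propensity at RNA-protein interfaces derived from contact
# source: statistics over a set of solved complexes. The original numeric
# source: tables are not published; replace this file with values recomputed
# source: from interface contact counts for exact reproduction. Defaults
# source: reflect relative stacking/contact surface of purines vs pyrimidines.
# alphabet: rna
A	1.05
C	0.90
G	1.20
U	0.95
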