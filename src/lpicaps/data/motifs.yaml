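# Default motif table: 18 lncRNA motifs + 11 protein motifs.
#
# RNA entries are RNA-binding-protein recognition elements written as
# IUPAC-degenerate strings (R={A,G}, Y={C,U}, W={A,U}, N=any, ...).
# The consensus patterns are drawn from the published SELEX/CLIP motif
# literature for each factor (e.g. Fox1 UGCAUG, Nova YCAY, PTB CUCUCU,
# ARE AUUUA, PUM UGUANAUA); where a factor's consensus varies between
# studies a single widely cited form was chosen.  The table is an editable
# config: the 18+11 layout and ordering are fixed contracts, the pattern
# strings are not.
#
# Protein entries are literal residue patterns; entries with several
# patterns count the sum of all their occurrences.  The final RNA entry is
# a group motif whose count is the sum of its member motifs' counts.
rna:
  - {name: Fox1,    patterns: [UGCAUG]}
  - {name: Nova,    patterns: [YCAY]}
  - {name: Slm2,    patterns: [UAAA, UUAA]}
  - {name: Fusip1,  patterns: [AGAGA]}
  - {name: PTB,     patterns: [CUCUCU]}
  - {name: ARE,     patterns: [AUUUA]}
  - {name: hnRNPA1, patterns: [UAGGGA, UAGGGU]}
  - {name: PUM,     patterns: [UGUANAUA]}
  - {name: U1A,     patterns: [AUUGCAC]}
  - {name: HuD,     patterns: [UUAUUU]}
  - {name: QKI,     patterns: [ACUAAY]}
  - {name: U2B,     patterns: [AUUGCAG]}
  - {name: SF1,     patterns: [UACUAAC]}
  - {name: HuR,     patterns: [UUUAUUU]}
  - {name: YB1,     patterns: [AACAUC]}
  - {name: AU,      patterns: [AU]}
  - {name: UG,      patterns: [UG]}
  - {name: combined, group: [Fox1, Nova, ARE, PUM, U1A]}
protein:
  - {name: H_or_R,  patterns: [H, R]}
  - {name: HR_RH,   patterns: [HR, RH]}
  - {name: E,       patterns: [E]}
  - {name: K,       patterns: [K]}
  - {name: H,       patterns: [H]}
  - {name: R,       patterns: [R]}
  - {name: EE,      patterns: [EE]}
  - {name: KK,      patterns: [KK]}
  - {name: RS_SR,   patterns: [RS, SR]}
  - {name: RGG,     patterns: [RGG]}
  - {name: YGG,     patterns: [YGG]}
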