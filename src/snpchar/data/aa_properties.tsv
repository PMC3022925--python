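# Overlapping physicochemical amino-acid classification (Taylor-style Venn,
# as used by multiple-alignment annotation tools). One residue per line:
# residue<TAB>comma-separated property labels. '*' (stop) carries no labels.
# Serine is deliberately not hydrophobic so that hydroxylic-column profiles
# separate cleanly from hydrophobic ones.
A	non-polar,hydrophobic,small,tiny
C	polar,hydrophobic,small,sulphur-containing
D	polar,hydrophilic,charged,negative,small
E	polar,hydrophilic,charged,negative
F	non-polar,hydrophobic,aromatic
G	non-polar,hydrophobic,small,tiny
H	polar,hydrophobic,charged,positive,aromatic
I	non-polar,hydrophobic,aliphatic
K	polar,hydrophilic,hydrophobic,charged,positive
L	non-polar,hydrophobic,aliphatic
M	non-polar,hydrophobic,sulphur-containing
N	polar,hydrophilic,small,amidic
P	non-polar,small
Q	polar,hydrophilic,amidic
R	polar,hydrophilic,charged,positive
S	polar,hydroxylic,small,tiny
T	polar,hydrophobic,hydroxylic,small
V	non-polar,hydrophobic,aliphatic,small
W	polar,hydrophobic,aromatic
Y	polar,hydrophobic,hydroxylic,aromatic
*
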