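# CHIP (STUB1) substitution mutation -> functional domain.
# Domains assigned by residue position: TPR 1-126, CC 127-229, Ubox 230-303.
# Identities beyond the clinically text-attested L123V, M240T, T246M are a
# curated synthetic stand-in for the published domain diagram; substitutions
# not listed here are assigned by the same residue-range rule at load time.
mutation,domain
E28K,TPR
N65S,TPR
A79D,TPR
A79T,TPR
L123V,TPR
M141V,CC
K145Q,CC
W147C,CC
L165F,CC
G229D,CC
M240T,Ubox
P243L,Ubox
T246M,Ubox
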