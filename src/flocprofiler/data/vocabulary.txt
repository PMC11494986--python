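# Controlled gene-symbol vocabulary for flocprofiler gene tables.
# One symbol per line; '#' starts a comment.  Annotation-tool output
# (e.g. DRAM/KOfam symbol dialects) is mapped onto these symbols before
# import — see docs/supplementary.md for the conversion recipe.

# denitrification
napA
napB
narG
narH
narI
nirS
nirK
norB
norC
nosZ

# DNRA
nirB
nirD
nrfA
nrfH

# assimilatory nitrate reduction
nas
nirA

# autotrophic nitrification
amoA
amoB
amoC
hao
nxr

# anammox
hzs
hdh

# nitrogen fixation (collapsed subunit symbol)
nif

# ammonium assimilation
glnA
gltB
gltD
gdh

# sulfur oxidation (sox cluster) and dissimilatory sulfite reduction
soxX
soxA
soxY
soxZ
soxB
soxC
soxD
dsrA
dsrB
sat
aprA
aprB

# generic placeholder symbol for genes whose annotation is a CAZy family
cazyme

# common single-copy housekeeping genes (used as neutral background)
recA
rpoB
gyrB
dnaK
ftsZ
rpsC
rplB
secY
infB
pheS
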