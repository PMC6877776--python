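# UMLS semantic type abbreviation -> semantic group code.
# Editable; defaults follow the standard UMLS semantic-group release.
# Lines: <semtype> <group>; '#' starts a comment.
amas GENE
gngm GENE
mosq GENE
nusq GENE
acab DISO
anab DISO
cgab DISO
comd DISO
dsyn DISO
emod DISO
fndg DISO
inpo DISO
mobd DISO
neop DISO
patf DISO
sosy DISO
aggp LIVB
amph LIVB
anim LIVB
arch LIVB
bact LIVB
bird LIVB
euka LIVB
famg LIVB
fish LIVB
fngs LIVB
grup LIVB
humn LIVB
mamm LIVB
orgm LIVB
plnt LIVB
podg LIVB
popg LIVB
prog LIVB
rept LIVB
virs LIVB
vtbt LIVB
aapp CHEM
bacs CHEM
chem CHEM
enzy CHEM
horm CHEM
inch CHEM
nnon CHEM
orch CHEM
phsu CHEM
ftcn CONC
idcn CONC
qlco CONC
qnco CONC
spco CONC
tmco CONC
celf PHYS
genf PHYS
moft PHYS
orgf PHYS
phsf PHYS
diap PROC
lbpr PROC
resa PROC
topp PROC
bpoc ANAT
celc ANAT
cell ANAT
tisu ANAT
geoa GEOG
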