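CC
CS
CSN
CST
DB
DD
EX
GE
II
JJ
JJR
JJT
MC
NN
NNP
NNS
PN
PND
PNG
PNR
RR
RRR
RRT
SYM
TO
VM
VBB
VBD
VBG
VBI
VBN
VBZ
VDB
VDD
VDG
VDI
VDN
VDZ
VHB
VHD
VHG
VHI
VHN
VHZ
VVB
VVD
VVG
VVGJ
VVGN
VVI
VVN
VVNJ
VVZ
(
)
,
.
:
``
''
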