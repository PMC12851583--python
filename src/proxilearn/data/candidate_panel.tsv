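candidate	n_trained_assigned	n_control_assigned	n_trained_all	reported_class
IFT-139	4	1	5	strong
ACR-2	1	0	4	strong
F46H5.3	3	2	4	strong
SAEG-1	2	0	4	strong
UEV-3	4	1	4	strong
AEX-3	0	0	3	strong
C30G12.6	0	0	3	strong
ELO-6	3	0	3	strong
ELP-1	2	1	3	strong
FSN-1	0	0	3	strong
GAP-2	2	0	3	strong
RIG-4	0	1	3	strong
TAG-52	1	0	3	strong
TAP-1	2	0	3	strong
VER-3	3	0	3	strong
ACC-3	1	0	2	weak
DLK-1	1	0	2	weak
GBB-2	2	0	2	weak
GPA-2	2	0	2	weak
RHO-1	2	1	2	weak
ACC-1	1	1	1	weak
GAP-1	1	0	1	weak
GLR-1	0	1	1	weak
KIN-2	1	0	1	weak
LGC-46	1	1	1	weak
MACO-1	1	0	1	weak
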