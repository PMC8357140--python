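old	new
SEPT1	SEPTIN1
SEPT2	SEPTIN2
SEPT3	SEPTIN3
SEPT4	SEPTIN4
SEPT5	SEPTIN5
SEPT6	SEPTIN6
SEPT7	SEPTIN7
SEPT8	SEPTIN8
SEPT9	SEPTIN9
SEPT10	SEPTIN10
SEPT11	SEPTIN11
SEPT12	SEPTIN12
SEPT14	SEPTIN14
MARCH1	MARCHF1
MARCH2	MARCHF2
MARCH3	MARCHF3
MARCH4	MARCHF4
MARCH5	MARCHF5
MARCH6	MARCHF6
MARCH7	MARCHF7
MARCH8	MARCHF8
MARCH9	MARCHF9
MARCH10	MARCHF10
MARCH11	MARCHF11
SEP15	SELENOF
DEC1	DELEC1
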