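# Synthetic stand-in cycling gene set ('small', 97 symbols).
# Placeholder identifiers; supply a curated list for real data.
CCG0001
CCG0002
CCG0003
CCG0004
CCG0005
CCG0006
CCG0007
CCG0008
CCG0009
CCG0010
CCG0011
CCG0012
CCG0013
CCG0014
CCG0015
CCG0016
CCG0017
CCG0018
CCG0019
CCG0020
CCG0021
CCG0022
CCG0023
CCG0024
CCG0025
CCG0026
CCG0027
CCG0028
CCG0029
CCG0030
CCG0031
CCG0032
CCG0033
CCG0034
CCG0035
CCG0036
CCG0037
CCG0038
CCG0039
CCG0040
CCG0041
CCG0042
CCG0043
CCG0044
CCG0045
CCG0046
CCG0047
CCG0048
CCG0049
CCG0050
CCG0051
CCG0052
CCG0053
CCG0054
CCG0055
CCG0056
CCG0057
CCG0058
CCG0059
CCG0060
CCG0061
CCG0062
CCG0063
CCG0064
CCG0065
CCG0066
CCG0067
CCG0068
CCG0069
CCG0070
CCG0071
CCG0072
CCG0073
CCG0074
CCG0075
CCG0076
CCG0077
CCG0078
CCG0079
CCG0080
CCG0081
CCG0082
CCG0083
CCG0084
CCG0085
CCG0086
CCG0087
CCG0088
CCG0089
CCG0090
CCG0091
CCG0092
CCG0093
CCG0094
CCG0095
CCG0096
CCG0097
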