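# Synthetic stand-in cycling gene set ('medium', 218 symbols).
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
CCG0098
CCG0099
CCG0100
CCG0101
CCG0102
CCG0103
CCG0104
CCG0105
CCG0106
CCG0107
CCG0108
CCG0109
CCG0110
CCG0111
CCG0112
CCG0113
CCG0114
CCG0115
CCG0116
CCG0117
CCG0118
CCG0119
CCG0120
CCG0121
CCG0122
CCG0123
CCG0124
CCG0125
CCG0126
CCG0127
CCG0128
CCG0129
CCG0130
CCG0131
CCG0132
CCG0133
CCG0134
CCG0135
CCG0136
CCG0137
CCG0138
CCG0139
CCG0140
CCG0141
CCG0142
CCG0143
CCG0144
CCG0145
CCG0146
CCG0147
CCG0148
CCG0149
CCG0150
CCG0151
CCG0152
CCG0153
CCG0154
CCG0155
CCG0156
CCG0157
CCG0158
CCG0159
CCG0160
CCG0161
CCG0162
CCG0163
CCG0164
CCG0165
CCG0166
CCG0167
CCG0168
CCG0169
CCG0170
CCG0171
CCG0172
CCG0173
CCG0174
CCG0175
CCG0176
CCG0177
CCG0178
CCG0179
CCG0180
CCG0181
CCG0182
CCG0183
CCG0184
CCG0185
CCG0186
CCG0187
CCG0188
CCG0189
CCG0190
CCG0191
CCG0192
CCG0193
CCG0194
CCG0195
CCG0196
CCG0197
CCG0198
CCG0199
CCG0200
CCG0201
CCG0202
CCG0203
CCG0204
CCG0205
CCG0206
CCG0207
CCG0208
CCG0209
CCG0210
CCG0211
CCG0212
CCG0213
CCG0214
CCG0215
CCG0216
CCG0217
CCG0218
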