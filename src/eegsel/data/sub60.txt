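E001
E005
E009
E013
E017
E020
E024
E028
E032
E036
E040
E044
E048
E052
E056
E059
E063
E067
E071
E075
E079
E083
E087
E091
E095
E098
E102
E106
E110
E114
E118
E122
E126
E130
E134
E137
E141
E145
E149
E153
E157
E161
E165
E169
E173
E176
E180
E184
E188
E192
E196
E200
E204
E208
E212
E215
E219
E223
E227
E231
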