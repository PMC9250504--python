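E001
E003
E005
E006
E008
E010
E012
E014
E015
E017
E019
E021
E023
E025
E026
E028
E030
E032
E034
E035
E037
E039
E041
E043
E044
E046
E048
E050
E052
E054
E055
E057
E059
E061
E063
E064
E066
E068
E070
E072
E073
E075
E077
E079
E081
E082
E084
E086
E088
E090
E092
E093
E095
E097
E099
E101
E102
E104
E106
E108
E110
E111
E113
E115
E117
E119
E121
E122
E124
E126
E128
E130
E131
E133
E135
E137
E139
E140
E142
E144
E146
E148
E150
E151
E153
E155
E157
E159
E160
E162
E164
E166
E168
E169
E171
E173
E175
E177
E178
E180
E182
E184
E186
E188
E189
E191
E193
E195
E197
E198
E200
E202
E204
E206
E207
E209
E211
E213
E215
E217
E218
E220
E222
E224
E226
E227
E229
E231
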