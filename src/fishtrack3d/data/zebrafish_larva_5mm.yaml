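length_mm: 5.0
stiff_fraction: 0.1
sections:
- s: 0.0
  trunk:
  - - 0.0
    - 0.05
  - - -0.035355
    - 0.035355
  - - -0.05
    - 0.0
  - - -0.035355
    - -0.035355
  - - -0.0
    - -0.05
  - - 0.035355
    - -0.035355
  - - 0.05
    - -0.0
  - - 0.035355
    - 0.035355
- s: 0.06
  trunk:
  - - 0.0
    - 0.25
  - - -0.159099
    - 0.176777
  - - -0.225
    - 0.0
  - - -0.159099
    - -0.176777
  - - -0.0
    - -0.25
  - - 0.159099
    - -0.176777
  - - 0.225
    - -0.0
  - - 0.159099
    - 0.176777
- s: 0.12
  trunk:
  - - 0.0
    - 0.4
  - - -0.212132
    - 0.297487
  - - -0.3
    - 0.05
  - - -0.212132
    - -0.197487
  - - -0.0
    - -0.3
  - - 0.212132
    - -0.197487
  - - 0.3
    - 0.05
  - - 0.212132
    - 0.297487
  eyes:
    a: 0.16
    b: 0.13
    n: 3.0
    offset_u: 0.3
    offset_v: 0.02
- s: 0.2
  trunk:
  - - 0.0
    - 0.47
  - - -0.219203
    - 0.355772
  - - -0.31
    - 0.08
  - - -0.219203
    - -0.195772
  - - -0.0
    - -0.31
  - - 0.219203
    - -0.195772
  - - 0.31
    - 0.08
  - - 0.219203
    - 0.355772
  eyes:
    a: 0.14
    b: 0.11
    n: 3.0
    offset_u: 0.28
    offset_v: 0.0
- s: 0.3
  trunk:
  - - 0.0
    - 0.455
  - - -0.194454
    - 0.345165
  - - -0.275
    - 0.08
  - - -0.194454
    - -0.185165
  - - -0.0
    - -0.295
  - - 0.194454
    - -0.185165
  - - 0.275
    - 0.08
  - - 0.194454
    - 0.345165
  finfold:
    a: 0.045
    b: 0.55
    offset_v: 0.1
- s: 0.45
  trunk:
  - - 0.0
    - 0.35
  - - -0.148492
    - 0.262132
  - - -0.21
    - 0.05
  - - -0.148492
    - -0.162132
  - - -0.0
    - -0.25
  - - 0.148492
    - -0.162132
  - - 0.21
    - 0.05
  - - 0.148492
    - 0.262132
  finfold:
    a: 0.04
    b: 0.55
    offset_v: 0.08
- s: 0.6
  trunk:
  - - 0.0
    - 0.245
  - - -0.106066
    - 0.179099
  - - -0.15
    - 0.02
  - - -0.106066
    - -0.139099
  - - -0.0
    - -0.205
  - - 0.106066
    - -0.139099
  - - 0.15
    - 0.02
  - - 0.106066
    - 0.179099
  finfold:
    a: 0.04
    b: 0.5
    offset_v: 0.05
- s: 0.75
  trunk:
  - - 0.0
    - 0.15
  - - -0.070711
    - 0.106066
  - - -0.1
    - 0.0
  - - -0.070711
    - -0.106066
  - - -0.0
    - -0.15
  - - 0.070711
    - -0.106066
  - - 0.1
    - -0.0
  - - 0.070711
    - 0.106066
  finfold:
    a: 0.035
    b: 0.42
    offset_v: 0.0
- s: 0.88
  trunk:
  - - 0.0
    - 0.09
  - - -0.042426
    - 0.06364
  - - -0.06
    - 0.0
  - - -0.042426
    - -0.06364
  - - -0.0
    - -0.09
  - - 0.042426
    - -0.06364
  - - 0.06
    - -0.0
  - - 0.042426
    - 0.06364
  finfold:
    a: 0.03
    b: 0.3
    offset_v: 0.0
- s: 0.96
  trunk:
  - - 0.0
    - 0.04
  - - -0.021213
    - 0.028284
  - - -0.03
    - 0.0
  - - -0.021213
    - -0.028284
  - - -0.0
    - -0.04
  - - 0.021213
    - -0.028284
  - - 0.03
    - -0.0
  - - 0.021213
    - 0.028284
  finfold:
    a: 0.02
    b: 0.12
    offset_v: 0.0
- s: 1.0
  trunk:
  - - 0.0
    - 0.01
  - - -0.007071
    - 0.007071
  - - -0.01
    - 0.0
  - - -0.007071
    - -0.007071
  - - -0.0
    - -0.01
  - - 0.007071
    - -0.007071
  - - 0.01
    - -0.0
  - - 0.007071
    - 0.007071
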