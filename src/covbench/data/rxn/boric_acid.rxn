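$RXN

      RDKit

  2  1
$MOL

     RDKit          2D

  3  2  0  3  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 B   0  0  0  0  0  0  0  0  0  1  0  0
    1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  2  0  0
   -1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  3  0  0
  1  2  6  0
  1  3  6  0
V    1 [B&X3:1]
V    2 [O&X2:2]
V    3 [O&X2:3]
M  STY  3   1 DAT   2 DAT   3 DAT
M  SAL   1  1   1
M  SED   1 [B&X3:1]
M  SAL   2  1   2
M  SED   2 [O&X2:2]
M  SAL   3  1   3
M  SED   3 [O&X2:3]
M  END
$MOL

     RDKit          2D

  2  1  0  2  0  0  0  0  0  0999 V2000
    1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0 91  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0 92  0  0
  1  2  6  0
V    1 [O&X2&H1:91]
V    2 [C&X4&H3:92]
M  STY  2   1 DAT   2 DAT
M  SAL   1  1   1
M  SED   1 [O&X2&H1:91]
M  SAL   2  1   2
M  SED   2 [C&X4&H3:92]
M  END
$MOL

     RDKit          2D

  5  4  0  5  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 B   0  0  0  0  0  0  0  0  0  1  0  0
    1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  2  0  0
   -1.2990    0.7500    0.0000 O   0  0  0  0  0  0  0  0  0  3  0  0
   -0.0000   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0 91  0  0
   -1.2990   -2.2500    0.0000 C   0  0  0  0  0  0  0  0  0 92  0  0
  1  2  6  0
  1  3  6  0
  1  4  6  0
  4  5  6  0
M  CHG  1   1  -1
V    1 [B&X4&-:1]
V    2 [O&X2:2]
V    3 [O&X2:3]
V    4 [O&X2:91]
V    5 [C&X4&H3:92]
M  STY  5   1 DAT   2 DAT   3 DAT   4 DAT   5 DAT
M  SAL   1  1   1
M  SED   1 [B&X4&-:1]
M  SAL   2  1   2
M  SED   2 [O&X2:2]
M  SAL   3  1   3
M  SED   3 [O&X2:3]
M  SAL   4  1   4
M  SED   4 [O&X2:91]
M  SAL   5  1   5
M  SED   5 [C&X4&H3:92]
M  END
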