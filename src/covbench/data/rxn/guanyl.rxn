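$RXN

      RDKit

  2  1
$MOL

     RDKit          2D

  4  3  0  4  0  0  0  0  0  0999 V2000
    1.2990    0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  1  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  2  0  0
   -1.2990    0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  3  0  0
   -0.0000   -1.5000    0.0000 N   0  0  0  0  0  0  0  0  0  4  0  0
  1  2  2  0
  2  3  6  0
  2  4  6  0
V    1 [N&X2:1]
V    2 [C&X3:2]
V    3 [N&X3:3]
V    4 [N&X3:4]
M  STY  4   1 DAT   2 DAT   3 DAT   4 DAT
M  SAL   1  1   1
M  SED   1 [N&X2:1]
M  SAL   2  1   2
M  SED   2 [C&X3:2]
M  SAL   3  1   3
M  SED   3 [N&X3:3]
M  SAL   4  1   4
M  SED   4 [N&X3:4]
M  END
$MOL

     RDKit          2D

  2  1  0  2  0  0  0  0  0  0999 V2000
    1.2990    0.7500    0.0000 S   0  0  0  0  0  0  0  0  0 91  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0 92  0  0
  1  2  6  0
V    1 [S&X2&H1:91]
V    2 [C&X4&H3:92]
M  STY  2   1 DAT   2 DAT
M  SAL   1  1   1
M  SED   1 [S&X2&H1:91]
M  SAL   2  1   2
M  SED   2 [C&X4&H3:92]
M  END
$MOL

     RDKit          2D

  6  5  0  6  0  0  0  0  0  0999 V2000
    3.3481    1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  1  0  0
    2.5981   -0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  2  0  0
    1.8481   -1.2990    0.0000 N   0  0  0  0  0  0  0  0  0  3  0  0
    3.8971   -0.7500    0.0000 N   0  0  0  0  0  0  0  0  0  4  0  0
    1.2990    0.7500    0.0000 S   0  0  0  0  0  0  0  0  0 91  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0 92  0  0
  1  2  6  0
  2  3  6  0
  2  4  6  0
  2  5  6  0
  5  6  6  0
V    1 [N&X3:1]
V    2 [C&X4:2]
V    3 [N&X3:3]
V    4 [N&X3:4]
V    5 [S&X2:91]
V    6 [C&X4&H3:92]
M  STY  6   1 DAT   2 DAT   3 DAT   4 DAT   5 DAT   6 DAT
M  SAL   1  1   1
M  SED   1 [N&X3:1]
M  SAL   2  1   2
M  SED   2 [C&X4:2]
M  SAL   3  1   3
M  SED   3 [N&X3:3]
M  SAL   4  1   4
M  SED   4 [N&X3:4]
M  SAL   5  1   5
M  SED   5 [S&X2:91]
M  SAL   6  1   6
M  SED   6 [C&X4&H3:92]
M  END
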