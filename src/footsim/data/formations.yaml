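# Role-box rectangle templates, one list per formation, for the side that
# defends the goal at x = -length/2 (team A).  Side B is obtained by point
# reflection through the pitch centre.  Coordinates are metres in the
# centre-origin pitch frame of a 110 x 60 pitch.  These extents are
# editable defaults: the goalkeeper box spans the penalty area and the
# defender/midfielder/forward bands split the pitch thirds with overlaps.
"3-5-2":
  - {role: G,    xmin: -55, ymin: -10, xmax: -45, ymax: 10}
  - {role: rCB,  xmin: -50, ymin: -30, xmax: -15, ymax: -8}
  - {role: CB,   xmin: -50, ymin: -11, xmax: -15, ymax: 11}
  - {role: lCB,  xmin: -50, ymin: 8,   xmax: -15, ymax: 30}
  - {role: rMF,  xmin: -25, ymin: -30, xmax: 20,  ymax: -16}
  - {role: rCMF, xmin: -25, ymin: -19, xmax: 20,  ymax: -4}
  - {role: CMF,  xmin: -25, ymin: -8,  xmax: 20,  ymax: 8}
  - {role: lCMF, xmin: -25, ymin: 4,   xmax: 20,  ymax: 19}
  - {role: lMF,  xmin: -25, ymin: 16,  xmax: 20,  ymax: 30}
  - {role: rF,   xmin: -5,  ymin: -30, xmax: 50,  ymax: 2}
  - {role: lF,   xmin: -5,  ymin: -2,  xmax: 50,  ymax: 30}
"4-4-2":
  - {role: G,    xmin: -55, ymin: -10, xmax: -45, ymax: 10}
  - {role: rB,   xmin: -50, ymin: -30, xmax: -15, ymax: -13}
  - {role: rCB,  xmin: -50, ymin: -16, xmax: -15, ymax: 1}
  - {role: lCB,  xmin: -50, ymin: -1,  xmax: -15, ymax: 16}
  - {role: lB,   xmin: -50, ymin: 13,  xmax: -15, ymax: 30}
  - {role: rMF,  xmin: -25, ymin: -30, xmax: 20,  ymax: -13}
  - {role: rCMF, xmin: -25, ymin: -16, xmax: 20,  ymax: 1}
  - {role: lCMF, xmin: -25, ymin: -1,  xmax: 20,  ymax: 16}
  - {role: lMF,  xmin: -25, ymin: 13,  xmax: 20,  ymax: 30}
  - {role: rF,   xmin: -5,  ymin: -30, xmax: 50,  ymax: 2}
  - {role: lF,   xmin: -5,  ymin: -2,  xmax: 50,  ymax: 30}
"4-3-3":
  - {role: G,    xmin: -55, ymin: -10, xmax: -45, ymax: 10}
  - {role: rB,   xmin: -50, ymin: -30, xmax: -15, ymax: -13}
  - {role: rCB,  xmin: -50, ymin: -16, xmax: -15, ymax: 1}
  - {role: lCB,  xmin: -50, ymin: -1,  xmax: -15, ymax: 16}
  - {role: lB,   xmin: -50, ymin: 13,  xmax: -15, ymax: 30}
  - {role: rMF,  xmin: -25, ymin: -30, xmax: 20,  ymax: -8}
  - {role: CMF,  xmin: -25, ymin: -11, xmax: 20,  ymax: 11}
  - {role: lMF,  xmin: -25, ymin: 8,   xmax: 20,  ymax: 30}
  - {role: rF,   xmin: -5,  ymin: -30, xmax: 50,  ymax: -8}
  - {role: CF,   xmin: -5,  ymin: -11, xmax: 50,  ymax: 11}
  - {role: lF,   xmin: -5,  ymin: 8,   xmax: 50,  ymax: 30}
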