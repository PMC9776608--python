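{
 "labels": [
  "AR",
  "PI3K",
  "PTEN",
  "p65",
  "IkB",
  "cMyc"
 ],
 "J": [
  1.5,
  2.0,
  -0.1,
  2.0,
  -0.1,
  0.8
 ],
 "d": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0
 ],
 "A": [
  [
   0.0,
   -1.0,
   0.0,
   0.5,
   0.0,
   0.7
  ],
  [
   0.0,
   0.0,
   -2.0,
   1.0,
   0.0,
   -0.5
  ],
  [
   0.0,
   2.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   -0.9,
   1.5,
   0.0,
   0.0,
   -3.0,
   0.5
  ],
  [
   0.0,
   0.0,
   0.0,
   3.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.5,
   0.0,
   1.0,
   0.0,
   0.0
  ]
 ]
}
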