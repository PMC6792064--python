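nodes:
- s
- a1
- a2
- a3
- a4
- a5
- a6
- b1
- b2
- b3
- b4
- b5
- b6
- c1
- c2
- c3
- c4
- f1
- f2
- f3
- t
source: s
sink: t
arcs:
- - s
  - a1
- - s
  - a2
- - s
  - a3
- - s
  - a4
- - s
  - a5
- - s
  - a6
- - a1
  - b1
- - a1
  - b2
- - a1
  - b3
- - a1
  - b4
- - a1
  - b5
- - a1
  - b6
- - a2
  - b1
- - a2
  - b2
- - a2
  - b3
- - a2
  - b4
- - a2
  - b5
- - a2
  - b6
- - a3
  - b1
- - a3
  - b2
- - a3
  - b3
- - a3
  - b4
- - a3
  - b5
- - a3
  - b6
- - a4
  - b1
- - a4
  - b2
- - a4
  - b3
- - a4
  - b4
- - a4
  - b5
- - a4
  - b6
- - a5
  - b1
- - a5
  - b2
- - a5
  - b3
- - a5
  - b4
- - a5
  - b5
- - a5
  - b6
- - a6
  - b1
- - a6
  - b2
- - a6
  - b3
- - a6
  - b4
- - a6
  - b5
- - a6
  - b6
- - b1
  - c1
- - b1
  - c2
- - b1
  - c3
- - b1
  - c4
- - b2
  - c1
- - b2
  - c2
- - b2
  - c3
- - b2
  - c4
- - b3
  - c1
- - b3
  - c2
- - b3
  - c3
- - b3
  - c4
- - b4
  - c1
- - b4
  - c2
- - b4
  - c3
- - b4
  - c4
- - b5
  - c1
- - b5
  - c2
- - b5
  - c3
- - b5
  - c4
- - b6
  - c1
- - b6
  - c2
- - b6
  - c3
- - b6
  - c4
- - c1
  - f1
- - c1
  - f2
- - c1
  - f3
- - c2
  - f1
- - c2
  - f2
- - c2
  - f3
- - c3
  - f1
- - c3
  - f2
- - c3
  - f3
- - c4
  - f1
- - c4
  - f2
- - f1
  - t
- - f2
  - t
- - f3
  - t
costs:
- 13.0
- 5.0
- 7.0
- 12.0
- 13.0
- 5.0
- 13.0
- 6.0
- 14.0
- 13.0
- 13.0
- 10.0
- 12.0
- 13.0
- 4.0
- 6.0
- 10.0
- 8.0
- 8.0
- 5.0
- 14.0
- 11.0
- 6.0
- 9.0
- 6.0
- 5.0
- 13.0
- 12.0
- 12.0
- 13.0
- 12.0
- 12.0
- 12.0
- 9.0
- 14.0
- 4.0
- 11.0
- 12.0
- 4.0
- 8.0
- 5.0
- 4.0
- 14.0
- 13.0
- 9.0
- 14.0
- 6.0
- 13.0
- 10.0
- 4.0
- 8.0
- 6.0
- 4.0
- 7.0
- 14.0
- 11.0
- 8.0
- 14.0
- 4.0
- 12.0
- 7.0
- 11.0
- 12.0
- 12.0
- 14.0
- 6.0
- 10.0
- 12.0
- 13.0
- 5.0
- 9.0
- 11.0
- 8.0
- 7.0
- 4.0
- 6.0
- 6.0
- 9.82
- 9.72
- 12.46
varied_arcs:
- 6
- 14
- 43
- 48
- 54
- 61
- 66
- 68
- 70
- 72
- 74
- 76
perturbed_better:
- 6
- 14
- 43
- 45
- 48
- 51
- 54
- 57
- 61
- 66
- 67
- 68
- 69
- 70
- 71
- 72
- 73
- 74
- 75
- 76
- 77
- 78
- 79
perturbed_worse:
- 0
- 1
- 2
- 3
- 4
- 5
- 6
- 7
- 8
- 9
- 10
- 11
- 12
- 13
- 14
- 15
- 16
- 17
- 18
- 19
- 20
- 21
- 22
- 43
- 45
- 48
- 51
- 54
- 57
- 61
- 66
- 67
- 68
- 69
- 70
- 71
- 72
- 73
- 74
- 75
- 76
- 77
- 78
- 79
noise_better: 0.15
noise_worse: 0.5
vary_sigma: 0.5
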