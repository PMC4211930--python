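strategy,dose,successes,totals
sp,none,5,27
za,none,3,18
ze,none,4,29
it,none,21,29
sp,minimum,32,43
za,minimum,34,38
ze,minimum,38,48
it,minimum,21,22
sp,medium,65,71
za,medium,65,73
ze,medium,36,42
it,medium,24,25
sp,maximum,43,49
za,maximum,66,74
ze,maximum,49,56
it,maximum,21,24
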