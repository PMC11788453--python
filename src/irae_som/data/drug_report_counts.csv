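drug,case,total,ratio,unit
Atezolizumab,3797,6692,56.7,4
Avelumab,361,597,60.5,5
Cemiplimab,17,31,54.8,5
Durvalumab,2554,3568,71.6,5
Ipilimumab,9315,12016,77.5,3
Nivolumab,16574,22944,72.2,2
Pembrolizumab,11487,17380,66.1,3
Tremelimumab,196,298,65.8,5
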