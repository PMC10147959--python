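{
  "compounds.tsv": "00526258c9d2b090c9970d59dd90ede2fe02b43a1cd38d61db21b91e18de04f1",
  "tms_derivatives.tsv": "88f27982dc37692c6e0479fdd205671dda518f474ce3c8d527ae9b42e0db7904",
  "tbdms_derivatives.tsv": "5d3170ee30d2c744307958d5038e63693df91658cad2983f415a7005105178ec"
}
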