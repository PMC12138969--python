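species,class,phylum,medium,endpoint,effect_type,concentration,conc_unit,duration,duration_unit,purity_pct,quality_pct,source_id
Example species,Insecta,Arthropoda,freshwater,LC50,acute,12.5,ug/L,4,days,99,90,example-1
Another species,Branchiopoda,Arthropoda,freshwater,EC50,acute,0.141,mg/L,48,h,95,80,example-2
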