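(t0:0.00600463433930008,(((t1:0.030053401255485435,(t5:0.10737006617146334,t6:0.18842500515159508):0.022207126238250784):0.3144673318069906,t2:0.05411358941882116):0.07358572736472967,t3:0.031214561205076416):0.03483728984023073,(t4:0.08997701549512001,t7:0.08835651222430084):0.007506150536528653);
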