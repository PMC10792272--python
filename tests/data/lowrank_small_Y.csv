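0.95891596958340297
1.3212912990182606
-2.5081467972837834
1.0181434738555051
-2.1822844461455708
-0.09577243104720759
0.99069106671214446
1.004782896878718
0.030441298779454676
-0.65117641993696274
1.6532392157800306
-1.6948589002686028
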