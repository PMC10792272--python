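-1.1239485124487127,-2.5593475414770586,-0.37343807475353819
-0.042436202516514365,-1.7744010832320622,-0.61118936028978232
0.086871239114312312,3.3756119784262189,1.159787572091602
2.6899953838111159,1.7998388611642044,-0.64562774881994744
-1.7680546637289449,0.79246173345086468,1.1273786708943099
-0.39779581325033753,-0.33769232995933496,0.070018012172314376
-1.5934112365410755,-3.1469274934660616,-0.35808493321063584
-0.67336085109171739,-2.0950907887921009,-0.42365517170930156
0.45202616146917418,0.4860692984042238,-0.043142167740967886
0.61889039587344818,1.570070978815693,0.26285332737771239
0.72309351544277056,-1.3172914465464707,-0.81453234939639507
-1.3486504836896893,0.64395924643776759,0.87400061916452143
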