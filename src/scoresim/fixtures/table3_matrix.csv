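site,bff,hhp,pmp,rbaps_draft,test_card
1,7,4,6.5,6,6.8
2,7,8,8.5,7,8.5
3,7,8,8.5,5,8.8
4,7,4.5,7,3.5,7.2
5,3,1,-0.5,-1,4.8
6,1.5,-3,-1.3,0,2.3
7,7.5,7,7,6,8.7
8,5,3,2,0,6.4
9,7.5,7,7.5,6,7.2
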