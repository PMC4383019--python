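{
 "table1.tsv": "b526cc62024cea5a31af4f515a9398646a1cc4a281d5511e62ca47213cd0e510",
 "table2.tsv": "b6ba07c31e4a2107493766d8a8341ac0758e889cfc821526aaa90c14c859b529"
}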