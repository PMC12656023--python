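{
  "rpf.csv": "f365741eef483828890e72b39e2514d847a2c0d822cf77fffd707e5758dcaf48",
  "table1.csv": "7c8f659bb4c85d40d951899bfd682488119dfa494fc971299435825d20aee68f",
  "table2.csv": "ef412b77f622b34135e21b7f7759afc2d2ab023825aa9d9b02fbc30d9227c3e1",
  "table3.csv": "bcd12e6994edb1f219cf21f01590f78a3647dd0cf0e752ef4e8af196d3ca34b1",
  "table4.csv": "36fa14f7029dba04ac28b9305767391da11d301e5b19ef65f821b8cf9cc04234",
  "table5.csv": "b630780d15ea409e446eb693f0163976b95575c72ffad13d0d005f045a42a9ec",
  "table6.csv": "758d1f520b3b6f785446a7b781687fd4bfcdd842b581b32e868d2281bf901a95",
  "table7.csv": "671764155991380a04a36c19b19cbe6e8b094792a76cd806934c77449a201c80"
}
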