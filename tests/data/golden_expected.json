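{
 "n_populations": 8,
 "n_pairs": 12,
 "Ar": [
  4.2,
  4.4,
  4.2,
  4.0,
  4.6,
  4.2,
  4.6,
  4.0
 ],
 "He": [
  0.6710144928,
  0.631884058,
  0.665942029,
  0.6007246377,
  0.631884058,
  0.5623188406,
  0.6463768116,
  0.5768115942
 ],
 "Ho": [
  0.65,
  0.55,
  0.6333333333,
  0.5833333333,
  0.6333333333,
  0.6166666667,
  0.6333333333,
  0.55
 ],
 "F": [
  0.0313174946,
  0.129587156,
  0.0489662677,
  0.0289505428,
  -0.002293578,
  -0.0966494845,
  0.0201793722,
  0.0464824121
 ],
 "Gst_dp": [
  0.1481849671,
  0.2622782865,
  0.1978548896,
  0.3307400065,
  0.3651908397,
  0.2121253111,
  0.2462033081,
  0.2953750486,
  0.3118811881,
  0.307571467,
  0.340929269,
  0.0695082676
 ],
 "Dps": [
  0.225,
  0.3,
  0.25,
  0.375,
  0.3583333333,
  0.3,
  0.3166666667,
  0.3583333333,
  0.35,
  0.325,
  0.3583333333,
  0.175
 ],
 "distance_m": [
  1621.3886219561,
  1397.2927289675,
  2498.4649349698,
  243.615276341,
  887.2799144321,
  1127.6733941362,
  699.2016599008,
  1054.240018039,
  894.8246139751,
  432.2554347473,
  849.0626089337,
  1252.0693552869
 ]
}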