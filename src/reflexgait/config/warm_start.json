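{
 "x": [
  4.156242314340303,
  0.9510105504078592,
  1.4619889843963771,
  10.0,
  3.453445249861965,
  1.1500266699729096,
  0.4522182544375315,
  5.980349083069111,
  2.3112583983043606,
  20.0,
  0.0,
  0.0,
  1.7931576371457765,
  0.5,
  0.18687933961000375,
  0.0,
  0.30102858435124885,
  0.18626711170605192,
  0.0,
  0.0859444554720704,
  0.4066009788667261,
  3.143137914679461,
  0.4,
  1.4590639505194514,
  1.043383561839366,
  1.0935596728110122,
  3.4009635670883447,
  1.3,
  0.4362854294083395,
  0.393656037034224,
  0.3740339863469365,
  0.0,
  0.18601288178555436,
  0.5,
  0.0,
  6.309557488628837,
  0.0,
  1.4769936716923087,
  1.3289185847326332,
  0.014646746203768983,
  0.14529857956200853,
  7.056184496446239,
  1.5679529330539188,
  0.0,
  2.9393733859112587,
  0.4,
  0.13917632949517406,
  0.0,
  0.3485002409048549,
  0.18483464149722667,
  0.0,
  0.0,
  -0.08474472005943197,
  0.40965313589063945,
  0.0,
  0.45,
  -0.2,
  1.12,
  0.4,
  -0.6,
  1.2,
  0.17857536887168446,
  0.5053443113602475,
  0.4204270249913066,
  -0.15673322516762084,
  2.0190603682391908,
  -0.6858266899515522,
  2.0,
  -0.05093697280091192,
  -1.5621060245662415,
  -5.0,
  -2.241257746060941,
  -4.232435860149433,
  -1.6138024902913823
 ],
 "note": "CMA-ES level-walking solution (desk-scale budget); seeds scenario optimizations and smoke tests",
 "scenario": {
  "load_fraction": 0.0,
  "incline_deg": 0.0,
  "target_speed": 1.5
 },
 "provenance": "shaped discovery + true-objective polish, 5-s rollouts"
}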