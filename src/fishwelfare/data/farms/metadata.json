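{
 "1": {
  "location": "indoor",
  "system": "RAS",
  "species": "rainbow trout",
  "purpose": "grow-out",
  "standard_length_cm": 19.5,
  "total_length_cm": 21.7,
  "body_weight_g": 132
 },
 "2": {
  "location": "indoor",
  "system": "RAS",
  "species": "rainbow trout",
  "purpose": "grow-out",
  "standard_length_cm": 19.6,
  "total_length_cm": 21.7,
  "body_weight_g": 111
 },
 "3": {
  "location": "outdoor",
  "system": "FTS",
  "species": "rainbow trout",
  "purpose": "grow-out",
  "standard_length_cm": 11.6,
  "total_length_cm": 13.5,
  "body_weight_g": 25.3
 },
 "4": {
  "location": "outdoor",
  "system": "FTS",
  "species": "rainbow trout",
  "purpose": "restocking",
  "standard_length_cm": 25,
  "total_length_cm": 27.6,
  "body_weight_g": 218
 },
 "5": {
  "location": "indoor",
  "system": "RAS",
  "species": "pikeperch",
  "purpose": "grow-out",
  "standard_length_cm": 25.2,
  "total_length_cm": 26.1,
  "body_weight_g": 154
 },
 "6": {
  "location": "indoor",
  "system": "RAS",
  "species": "pikeperch",
  "purpose": "grow-out",
  "standard_length_cm": 28.7,
  "total_length_cm": 32.4,
  "body_weight_g": 198
 }
}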