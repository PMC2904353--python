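{
 "1.4": {
  "A": 107.47633323662103,
  "C": 123.69550085939184,
  "D": 129.60243269409574,
  "E": 142.11380941489455,
  "F": 171.01331803615219,
  "G": 71.02004330128526,
  "H": 156.0207733269234,
  "I": 148.7610786070876,
  "K": 156.0207733269234,
  "L": 148.7610786070876,
  "M": 156.0207733269234,
  "N": 135.634186288112,
  "P": 129.60243269409574,
  "Q": 148.7610786070876,
  "R": 171.01331803615219,
  "S": 118.05629209487498,
  "T": 129.60243269409574,
  "V": 135.634186288112,
  "W": 195.52081792415674,
  "Y": 178.860322192843
 },
 "2.0": {
  "A": 124.22133404040514,
  "C": 143.03918343808752,
  "D": 150.32989384555515,
  "E": 165.35544475552106,
  "F": 198.75545104329743,
  "G": 78.21102667739808,
  "H": 181.49237961978787,
  "I": 173.16469733577156,
  "K": 181.49237961978787,
  "L": 173.16469733577156,
  "M": 181.49237961978787,
  "N": 157.60736275414715,
  "P": 150.32989384555515,
  "Q": 173.16469733577156,
  "R": 198.75545104329743,
  "S": 136.79942970686602,
  "T": 150.32989384555515,
  "V": 157.60736275414715,
  "W": 226.54342931203664,
  "Y": 207.58411399716306
 }
}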