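# Default 8-plex iTRAQ design: five fibroblast cultures on channels 113-117
# (113 is the reference, so its ratio column is identically 1) and three
# colon cancer epithelial cell lines on channels 118, 119 and 121.
channels: ["113", "114", "115", "116", "117", "118", "119", "121"]
reference: "113"
group_of:
  "113": fibroblast
  "114": fibroblast
  "115": fibroblast
  "116": fibroblast
  "117": fibroblast
  "118": cancer
  "119": cancer
  "121": cancer
sample_of:
  "113": CCD-18Co
  "114": 0426_NF
  "115": 0426_CAF
  "116": 1031_NF
  "117": 1031_CAF
  "118": SW620
  "119": HT-29
  "121": LoVo
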