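{
  "_comment": [
    "Default 19-channel infant montage: 7 LED sources and 7 detectors over frontal,",
    "temporal and parietal cortex, 3 cm source-detector separation, 10-10 placement.",
    "Channel region/hemisphere labels follow the activation-table semantics:",
    "1/2 left prefrontal, 3/4 right prefrontal/inferior-frontal, 6/7 left inferior",
    "frontal, 5 right posterior superior temporal, 12 its left-hemisphere partner,",
    "8/13 left temporal, 16 postcentral. Channels 9 and 16 are reported bilaterally",
    "in the source montage; each is labelled here by its dominant column (9 -> right",
    "frontal, 16 -> midline parietal) and the ambiguity is noted rather than resolved.",
    "Remaining channels without an explicit label are assigned to parietal.",
    "Optode indices are a consistent but nominal pairing (no coordinates are claimed)."
  ],
  "source_detector_distance": 3.0,
  "channels": [
    {"id": 1,  "source": 1, "detector": 1, "region": "frontal",  "hemisphere": "left"},
    {"id": 2,  "source": 1, "detector": 2, "region": "frontal",  "hemisphere": "left"},
    {"id": 3,  "source": 3, "detector": 3, "region": "frontal",  "hemisphere": "right"},
    {"id": 4,  "source": 3, "detector": 4, "region": "frontal",  "hemisphere": "right"},
    {"id": 5,  "source": 6, "detector": 6, "region": "temporal", "hemisphere": "right"},
    {"id": 6,  "source": 2, "detector": 1, "region": "frontal",  "hemisphere": "left"},
    {"id": 7,  "source": 2, "detector": 2, "region": "frontal",  "hemisphere": "left"},
    {"id": 8,  "source": 5, "detector": 5, "region": "temporal", "hemisphere": "left"},
    {"id": 9,  "source": 4, "detector": 3, "region": "frontal",  "hemisphere": "right"},
    {"id": 10, "source": 4, "detector": 4, "region": "frontal",  "hemisphere": "right"},
    {"id": 11, "source": 6, "detector": 7, "region": "temporal", "hemisphere": "right"},
    {"id": 12, "source": 5, "detector": 6, "region": "temporal", "hemisphere": "left"},
    {"id": 13, "source": 5, "detector": 7, "region": "temporal", "hemisphere": "left"},
    {"id": 14, "source": 7, "detector": 1, "region": "parietal", "hemisphere": "left"},
    {"id": 15, "source": 7, "detector": 6, "region": "temporal", "hemisphere": "right"},
    {"id": 16, "source": 7, "detector": 7, "region": "parietal", "hemisphere": "midline"},
    {"id": 17, "source": 7, "detector": 2, "region": "parietal", "hemisphere": "right"},
    {"id": 18, "source": 4, "detector": 6, "region": "parietal", "hemisphere": "left"},
    {"id": 19, "source": 3, "detector": 5, "region": "parietal", "hemisphere": "right"}
  ],
  "symmetric_pairs": [
    [1, 3], [2, 4], [6, 9], [7, 10],
    [12, 5], [8, 11], [13, 15]
  ]
}
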