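[
  {
    "class": "AZFa",
    "absent": ["sY1317", "sY1316", "sY1234"],
    "flanks": ["sY1250", "sY1231"],
    "comment": "Curated approximation: the recurrent HERV15 provirus A/B recombination deletion removes USP9Y and DDX3Y (DBY) while UTY is retained. Marker membership is an editable mapping of the classical AZFa interval onto this 51-marker panel, not a verbatim published pattern."
  },
  {
    "class": "P5/proximal-P1",
    "absent": ["sY1235", "sY1260", "sY1237", "sY121", "sY1322", "sY280", "sY1233", "sY627", "sY1682"],
    "flanks": ["sY1234", "sY254", "sY1291"],
    "comment": "Curated approximation of the AZFb (P5/proximal-P1) deletion: XKRY, CDY2, HSFY, the P4-distal region, CYorf15, SMCY, EIF1AY, RBMY and RPS4Y2 markers lost; AZFc content retained."
  },
  {
    "class": "P5/distal-P1",
    "absent": ["sY1235", "sY1260", "sY1237", "sY121", "sY1322", "sY280", "sY1233", "sY627", "sY1682", "sY1258", "sY1161", "sY1197", "sY1191", "sY1035", "sY1318", "sY254", "sY1291", "sY1125", "sY1054", "sY1190", "sY1263", "sY1206", "sY1201"],
    "flanks": ["sY1234", "sY1246"],
    "comment": "Curated approximation of the AZFb+c (P5/distal-P1) deletion: the P5/proximal-P1 interval plus the whole AZFc amplicon region."
  },
  {
    "class": "AZFc",
    "absent": ["sY1258", "sY1161", "sY1191", "sY1035", "sY1318", "sY254", "sY1291", "sY1125", "sY1054", "sY1190", "sY1263", "sY1206"],
    "flanks": ["sY142", "sY1201", "sY1233"],
    "comment": "Curated approximation of the classical b2/b4 AZFc deletion removing the DAZ, BPY2 and CDY1 amplicon content between blue amplicons b2 and b4."
  },
  {
    "class": "gr/gr",
    "absent": ["sY1291"],
    "flanks": ["sY1191", "sY1206", "sY1201", "sY254"],
    "comment": "Curated approximation: the gr/gr partial-AZFc deletion removes the red/gray boundary marker sY1291 while sY1191 and the distal amplicon boundaries remain; multicopy gene markers (DAZ, CDY1) still amplify from retained copies."
  },
  {
    "class": "b2/b3",
    "absent": ["sY1191"],
    "flanks": ["sY1291", "sY254", "sY1206"],
    "comment": "Curated approximation: the b2/b3 partial-AZFc deletion removes unique sequence u3 (sY1191) while sY1291 remains."
  },
  {
    "class": "b1/b2",
    "absent": ["sY1258", "sY1161", "sY1197"],
    "flanks": ["sY1191", "sY1291"],
    "comment": "Curated approximation: the b1/b2 deletion removes the u1/b1 boundary, PRY and the internal P3 boundary while the distal AZFc amplicons remain."
  },
  {
    "class": "TSPY-TSPY",
    "absent": ["sY276", "sY1238"],
    "flanks": ["sY1240", "sY1250", "sY1256"],
    "comment": "Curated approximation: recombination between TSPY repeat copies on Yp deletes the intervening AMELY/TBL1Y interval; the TSPY array itself (multicopy) still amplifies."
  }
]
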