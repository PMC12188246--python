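{
  "id": "bsw3",
  "notes": "Core BMP-SOX9-WNT digit-interdigit model: interdigit BMP2 promotes SOX9 in digit territory, SOX9 restricts BMP2 and WNT2 to the interdigit, and WNT signaling (through cell-autonomous beta-catenin) represses SOX9.",
  "nodes": [
    {
      "name": "BMP2",
      "diffusible": true,
      "diffusion": 30.0,
      "role": "ligand"
    },
    {
      "name": "SOX9",
      "diffusible": false,
      "diffusion": 0.0,
      "role": "transcription_factor"
    },
    {
      "name": "WNT2",
      "diffusible": true,
      "diffusion": 1.0,
      "role": "ligand"
    },
    {
      "name": "CTNNB1",
      "diffusible": false,
      "diffusion": 0.0,
      "role": "transcription_factor"
    }
  ],
  "edges": [
    {
      "source": "BMP2",
      "target": "SOX9",
      "sign": "+",
      "tested": true
    },
    {
      "source": "SOX9",
      "target": "BMP2",
      "sign": "-",
      "tested": true
    },
    {
      "source": "SOX9",
      "target": "WNT2",
      "sign": "-",
      "tested": true
    },
    {
      "source": "WNT2",
      "target": "CTNNB1",
      "sign": "+",
      "tested": true
    },
    {
      "source": "CTNNB1",
      "target": "SOX9",
      "sign": "-",
      "tested": true
    }
  ]
}
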