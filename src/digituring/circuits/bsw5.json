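{
  "id": "bsw5",
  "notes": "Extended BMP-SOX9-WNT model with SULF1 downstream of SOX9 repressing the diffusible WNT2 ligand in the digit mesenchyme (hypothetical arrows), and beta-catenin acting cell-autonomously; functions as a substrate-depletion Turing system with BMP2 as the substrate.",
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
    },
    {
      "name": "SULF1",
      "diffusible": false,
      "diffusion": 0.0,
      "role": "modulator"
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
    },
    {
      "source": "SOX9",
      "target": "SULF1",
      "sign": "+",
      "tested": false
    },
    {
      "source": "SULF1",
      "target": "WNT2",
      "sign": "-",
      "tested": false
    }
  ]
}
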