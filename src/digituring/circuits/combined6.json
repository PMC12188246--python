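{
  "id": "combined6",
  "notes": "Merged network: the four-node WNT circuit combined with the five-node extended BMP-SOX9-WNT circuit (six nodes in total); the modulator SULF1 and antagonist SFRP2 pattern out-of-phase in digit and interdigit territories.",
  "nodes": [
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
      "name": "SFRP2",
      "diffusible": true,
      "diffusion": 30.0,
      "role": "antagonist"
    },
    {
      "name": "SULF1",
      "diffusible": false,
      "diffusion": 0.0,
      "role": "modulator"
    },
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
    }
  ],
  "edges": [
    {
      "source": "WNT2",
      "target": "CTNNB1",
      "sign": "+",
      "tested": true
    },
    {
      "source": "CTNNB1",
      "target": "WNT2",
      "sign": "+",
      "tested": true
    },
    {
      "source": "CTNNB1",
      "target": "SFRP2",
      "sign": "+",
      "tested": true
    },
    {
      "source": "SFRP2",
      "target": "WNT2",
      "sign": "-",
      "tested": true
    },
    {
      "source": "CTNNB1",
      "target": "SULF1",
      "sign": "-",
      "tested": true
    },
    {
      "source": "SULF1",
      "target": "WNT2",
      "sign": "-",
      "tested": true
    },
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
    }
  ]
}
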