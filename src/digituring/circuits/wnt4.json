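{
  "id": "wnt4",
  "notes": "The three-node WNT circuit extended by the modulator SULF1, expressed in the digit territory (out-of-phase with SFRP2) where WNT/beta-catenin activity is low, acting as a negative modulator of WNT2.",
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
    }
  ]
}
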