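{
  "id": "wnt3",
  "notes": "Three-node WNT circuit: diffusible WNT2 ligand signals through cell-autonomous beta-catenin, which sustains ligand production and induces the fast-diffusing extracellular antagonist SFRP2; a classical activator-inhibitor module with all three components in-phase in the interdigit.",
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
    }
  ]
}
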