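{
  "_comment": [
    "Default degenerate patterns for the conserved intein sequence blocks.",
    "These are advisory annotation defaults, not filters: block boundaries are",
    "not defined numerically anywhere authoritative, so the patterns below are",
    "deliberately loose placeholders meant to be overridden from a config file",
    "refined against a family alignment. Pattern language: uppercase letter =",
    "literal residue; [XYZ] = allowed class; {XYZ} = excluded class; x = any.",
    "anchor: 'start'/'end' pins the match to the fragment terminus. window:",
    "optional [lo, hi) fractional region of the fragment to search."
  ],
  "motifs": [
    {"motif_id": "A", "target": "intN", "pattern": "[CST][LIVMAFG]x[DEGNSQTK]", "anchor": "start", "window": null},
    {"motif_id": "B", "target": "intN", "pattern": "TxxH", "anchor": null, "window": [0.2, 0.8]},
    {"motif_id": "NX", "target": "intN", "pattern": "H", "anchor": null, "window": [0.6, 1.0]},
    {"motif_id": "F", "target": "intC", "pattern": "[LIVMFY][DN][LIVMAGST]", "anchor": null, "window": null},
    {"motif_id": "G", "target": "intC", "pattern": "[VLIFMYAGSTNDH][HNQSRK]N", "anchor": "end", "window": null}
  ]
}
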