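{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tpcurve survival table CSV columns",
  "description": "Column contract for individual-level survival CSVs. One row per assayed individual; comma-separated, UTF-8, header row mandatory, '.' decimal mark.",
  "type": "object",
  "properties": {
    "block": {"type": "string", "description": "Experimental block label (categorical)."},
    "vial": {"type": "string", "description": "Vial label; unique within block x fert_temp x embryo_temp x assay_temp."},
    "fert_temp": {"type": "number", "description": "Temperature at fertilization, degrees Celsius (categorical factor in modeling)."},
    "embryo_temp": {"type": "number", "description": "Temperature at embryogenesis, degrees Celsius (categorical factor in modeling)."},
    "assay_temp": {"type": "number", "description": "Assay temperature, degrees Celsius (continuous axis)."},
    "outcome": {"type": "integer", "enum": [0, 1], "description": "1 = survived to completion of development, 0 = died beforehand."}
  },
  "required": ["block", "vial", "fert_temp", "embryo_temp", "assay_temp", "outcome"]
}
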