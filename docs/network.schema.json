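{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Comorbidity network export",
 "type": "object",
 "required": ["stratum", "density", "nodes", "edges"],
 "properties": {
  "stratum": {"type": "string"},
  "density": {"type": "number"},
  "provenance": {"type": "object"},
  "nodes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["disease", "prevalence", "connectivity"],
    "properties": {
     "disease": {"type": "string"},
     "prevalence": {"type": "number"},
     "connectivity": {"type": "number"}
    }
   }
  },
  "edges": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["i", "j", "mean_phi", "significant"],
    "properties": {
     "i": {"type": "string"},
     "j": {"type": "string"},
     "mean_phi": {"type": "number", "exclusiveMinimum": 0},
     "significant": {"const": true}
    }
   }
  }
 }
}
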