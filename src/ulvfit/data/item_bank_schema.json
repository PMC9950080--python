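{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ulvfit item-bank document",
 "type": "object",
 "required": ["activities", "items"],
 "properties": {
  "activities": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["activity_id", "name", "category", "m", "visibility_axis"],
    "properties": {
     "activity_id": {"type": "string"},
     "name": {"type": "string"},
     "category": {"enum": ["spatial_localization", "motion_detection", "direction_of_motion"]},
     "m": {"type": "integer", "minimum": 2, "maximum": 4},
     "visibility_axis": {"enum": ["contrast_percent", "duration_seconds", "flicker_hz", "movement_amplitude", "grayscale_level"]}
    }
   }
  },
  "items": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["item_id", "activity_id", "level", "visibility_value"],
    "properties": {
     "item_id": {"type": "string"},
     "activity_id": {"type": "string"},
     "level": {"enum": [1, 2, 3]},
     "visibility_value": {"type": "number"}
    }
   }
  }
 }
}
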