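{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "pat-session/1",
  "title": "Phase adjustment task session",
  "type": "object",
  "required": ["participant_id", "dataset_id", "task", "baseline_beats_ms", "trials"],
  "properties": {
    "schema": {"const": "pat-session/1"},
    "participant_id": {"type": "string"},
    "dataset_id": {"type": ["integer", "string"]},
    "task": {"enum": ["PAT", "screener"]},
    "baseline_duration_s": {"type": "number", "exclusiveMinimum": 0},
    "baseline_beats_ms": {
      "type": "array",
      "items": {"type": "number"},
      "description": "strictly increasing heartbeat timestamps (ms from baseline start)"
    },
    "trials": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["trial_index", "is_practice", "delay_trace", "duration_s"],
        "properties": {
          "trial_index": {"type": "integer", "minimum": 1},
          "is_practice": {"type": "boolean"},
          "delay_trace": {"type": "array", "items": {"type": "number"}},
          "final_delay_ms": {"type": ["number", "null"]},
          "beat_times_ms": {"type": "array", "items": {"type": "number"}},
          "hr_samples": {"type": "array", "items": {"type": "number"}},
          "confidence": {"type": ["integer", "null"], "minimum": 0, "maximum": 9},
          "duration_s": {"type": "number", "exclusiveMinimum": 0},
          "body_map_location": {"type": ["string", "null"]}
        }
      }
    },
    "metadata": {"type": "object"}
  }
}
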