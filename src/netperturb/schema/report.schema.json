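{
 "$defs": {
  "ConsistencySummary": {
   "properties": {
    "alpha": {
     "title": "Alpha",
     "type": "number"
    },
    "bidirected_added": {
     "title": "Bidirected Added",
     "type": "integer"
    },
    "failure_fraction": {
     "title": "Failure Fraction",
     "type": "number"
    },
    "max_cond": {
     "title": "Max Cond",
     "type": "integer"
    },
    "n_failed": {
     "title": "N Failed",
     "type": "integer"
    },
    "n_skipped": {
     "title": "N Skipped",
     "type": "integer"
    },
    "n_tests": {
     "title": "N Tests",
     "type": "integer"
    },
    "repaired": {
     "title": "Repaired",
     "type": "boolean"
    }
   },
   "required": [
    "n_tests",
    "n_failed",
    "failure_fraction",
    "alpha",
    "max_cond",
    "n_skipped",
    "repaired",
    "bidirected_added"
   ],
   "title": "ConsistencySummary",
   "type": "object"
  },
  "EstimateSection": {
   "properties": {
    "adjustment_set": {
     "anyOf": [
      {
       "items": {
        "type": "string"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Adjustment Set"
    },
    "distribution": {
     "anyOf": [
      {
       "additionalProperties": true,
       "type": "object"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Distribution"
    },
    "estimator": {
     "title": "Estimator",
     "type": "string"
    },
    "interval": {
     "anyOf": [
      {
       "items": {
        "type": "number"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Interval"
    },
    "level": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Level"
    },
    "n": {
     "title": "N",
     "type": "integer"
    },
    "point": {
     "title": "Point",
     "type": "number"
    }
   },
   "required": [
    "estimator",
    "point",
    "n"
   ],
   "title": "EstimateSection",
   "type": "object"
  },
  "IdentifiabilitySection": {
   "properties": {
    "estimand": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Estimand"
    },
    "estimand_tree": {
     "anyOf": [
      {
       "additionalProperties": true,
       "type": "object"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Estimand Tree"
    },
    "original": {
     "title": "Original",
     "type": "string"
    },
    "repaired": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Repaired"
    },
    "witness": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Witness"
    }
   },
   "required": [
    "original"
   ],
   "title": "IdentifiabilitySection",
   "type": "object"
  },
  "ReductionSection": {
   "properties": {
    "bidirected_after": {
     "title": "Bidirected After",
     "type": "integer"
    },
    "bidirected_before": {
     "title": "Bidirected Before",
     "type": "integer"
    },
    "directed_after": {
     "title": "Directed After",
     "type": "integer"
    },
    "directed_before": {
     "title": "Directed Before",
     "type": "integer"
    },
    "nodes_after": {
     "title": "Nodes After",
     "type": "integer"
    },
    "nodes_before": {
     "title": "Nodes Before",
     "type": "integer"
    },
    "nuisance": {
     "items": {
      "type": "string"
     },
     "title": "Nuisance",
     "type": "array"
    }
   },
   "required": [
    "nuisance",
    "nodes_before",
    "nodes_after",
    "directed_before",
    "directed_after",
    "bidirected_before",
    "bidirected_after"
   ],
   "title": "ReductionSection",
   "type": "object"
  },
  "StepStatus": {
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "reason": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Reason"
    },
    "seconds": {
     "default": 0.0,
     "title": "Seconds",
     "type": "number"
    },
    "status": {
     "enum": [
      "done",
      "skipped"
     ],
     "title": "Status",
     "type": "string"
    }
   },
   "required": [
    "name",
    "status"
   ],
   "title": "StepStatus",
   "type": "object"
  },
  "WorkflowConfig": {
   "additionalProperties": false,
   "properties": {
    "alpha": {
     "default": 0.01,
     "exclusiveMaximum": 1.0,
     "exclusiveMinimum": 0.0,
     "title": "Alpha",
     "type": "number"
    },
    "assume_linear": {
     "default": true,
     "title": "Assume Linear",
     "type": "boolean"
    },
    "bootstrap": {
     "default": 1000,
     "minimum": 0,
     "title": "Bootstrap",
     "type": "integer"
    },
    "ci_policy": {
     "default": "ancestors",
     "enum": [
      "ancestors",
      "all-observables"
     ],
     "title": "Ci Policy",
     "type": "string"
    },
    "estimator": {
     "default": "auto",
     "enum": [
      "auto",
      "linear",
      "outcome_regression",
      "ipw",
      "aipw",
      "plugin"
     ],
     "title": "Estimator",
     "type": "string"
    },
    "fdr": {
     "default": false,
     "title": "Fdr",
     "type": "boolean"
    },
    "level": {
     "default": 0.95,
     "exclusiveMaximum": 1.0,
     "exclusiveMinimum": 0.0,
     "title": "Level",
     "type": "number"
    },
    "max_cond": {
     "default": 3,
     "minimum": 0,
     "title": "Max Cond",
     "type": "integer"
    },
    "repair": {
     "default": true,
     "title": "Repair",
     "type": "boolean"
    },
    "seed": {
     "default": 0,
     "title": "Seed",
     "type": "integer"
    }
   },
   "title": "WorkflowConfig",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "config": {
   "$ref": "#/$defs/WorkflowConfig"
  },
  "consistency": {
   "anyOf": [
    {
     "$ref": "#/$defs/ConsistencySummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "estimate": {
   "anyOf": [
    {
     "$ref": "#/$defs/EstimateSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "exposure": {
   "title": "Exposure",
   "type": "string"
  },
  "identifiability": {
   "anyOf": [
    {
     "$ref": "#/$defs/IdentifiabilitySection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "intervention": {
   "items": {
    "type": "number"
   },
   "title": "Intervention",
   "type": "array"
  },
  "outcome": {
   "title": "Outcome",
   "type": "string"
  },
  "query_form": {
   "title": "Query Form",
   "type": "string"
  },
  "reduction": {
   "anyOf": [
    {
     "$ref": "#/$defs/ReductionSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "steps": {
   "items": {
    "$ref": "#/$defs/StepStatus"
   },
   "title": "Steps",
   "type": "array"
  },
  "warnings": {
   "items": {
    "type": "string"
   },
   "title": "Warnings",
   "type": "array"
  }
 },
 "required": [
  "exposure",
  "outcome",
  "query_form",
  "intervention",
  "config",
  "steps"
 ],
 "title": "WorkflowReport",
 "type": "object"
}
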