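{
 "$defs": {
  "FamilyParalogyBlock": {
   "properties": {
    "cluster_modes": {
     "additionalProperties": {
      "type": "string"
     },
     "title": "Cluster Modes",
     "type": "object"
    },
    "family": {
     "title": "Family",
     "type": "string"
    },
    "mode_tally": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Mode Tally",
     "type": "object"
    },
    "multi_cluster_sizes": {
     "items": {
      "type": "integer"
     },
     "title": "Multi Cluster Sizes",
     "type": "array"
    },
    "n_clusters": {
     "title": "N Clusters",
     "type": "integer"
    },
    "n_in_clusters": {
     "title": "N In Clusters",
     "type": "integer"
    },
    "n_members": {
     "title": "N Members",
     "type": "integer"
    },
    "pct_paralogs": {
     "title": "Pct Paralogs",
     "type": "number"
    }
   },
   "required": [
    "family",
    "n_members",
    "n_in_clusters",
    "pct_paralogs",
    "n_clusters",
    "multi_cluster_sizes",
    "cluster_modes",
    "mode_tally"
   ],
   "title": "FamilyParalogyBlock",
   "type": "object"
  },
  "InventoryBlock": {
   "properties": {
    "dual_specificity_policy": {
     "default": "repeated-per-family",
     "title": "Dual Specificity Policy",
     "type": "string"
    },
    "ipd_counts_by_family": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Ipd Counts By Family",
     "type": "object"
    },
    "n_ipds": {
     "title": "N Ipds",
     "type": "integer"
    },
    "n_named": {
     "title": "N Named",
     "type": "integer"
    },
    "n_tfs": {
     "title": "N Tfs",
     "type": "integer"
    },
    "pct_named": {
     "title": "Pct Named",
     "type": "number"
    },
    "pct_unnamed": {
     "title": "Pct Unnamed",
     "type": "number"
    },
    "sp_counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Sp Counts",
     "type": "object"
    },
    "tf_counts_by_family": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Tf Counts By Family",
     "type": "object"
    },
    "tm_counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Tm Counts",
     "type": "object"
    }
   },
   "required": [
    "n_tfs",
    "n_ipds",
    "tf_counts_by_family",
    "ipd_counts_by_family",
    "n_named",
    "pct_named",
    "pct_unnamed",
    "sp_counts",
    "tm_counts"
   ],
   "title": "InventoryBlock",
   "type": "object"
  },
  "OrthologyBlock": {
   "properties": {
    "n_confirmed": {
     "title": "N Confirmed",
     "type": "integer"
    },
    "n_queries": {
     "title": "N Queries",
     "type": "integer"
    },
    "pct_confirmed": {
     "title": "Pct Confirmed",
     "type": "number"
    }
   },
   "required": [
    "n_queries",
    "n_confirmed",
    "pct_confirmed"
   ],
   "title": "OrthologyBlock",
   "type": "object"
  },
  "ReconciliationBlock": {
   "properties": {
    "counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Counts",
     "type": "object"
    },
    "event_counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Event Counts",
     "type": "object"
    },
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "percentages": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Percentages",
     "type": "object"
    }
   },
   "required": [
    "n_genes",
    "counts",
    "percentages",
    "event_counts"
   ],
   "title": "ReconciliationBlock",
   "type": "object"
  },
  "ShiftBlock": {
   "properties": {
    "fc": {
     "title": "Fc",
     "type": "number"
    },
    "global_shift": {
     "title": "Global Shift",
     "type": "boolean"
    },
    "n_down": {
     "title": "N Down",
     "type": "integer"
    },
    "n_up": {
     "title": "N Up",
     "type": "integer"
    },
    "ratio": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Ratio"
    },
    "sample_a": {
     "title": "Sample A",
     "type": "string"
    },
    "sample_b": {
     "title": "Sample B",
     "type": "string"
    },
    "score": {
     "title": "Score",
     "type": "number"
    }
   },
   "required": [
    "sample_a",
    "sample_b",
    "fc",
    "n_up",
    "n_down",
    "ratio",
    "score",
    "global_shift"
   ],
   "title": "ShiftBlock",
   "type": "object"
  },
  "SilenceBlock": {
   "properties": {
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "n_silent": {
     "title": "N Silent",
     "type": "integer"
    },
    "pct_silent": {
     "title": "Pct Silent",
     "type": "number"
    },
    "silent_genes": {
     "items": {
      "type": "string"
     },
     "title": "Silent Genes",
     "type": "array"
    },
    "strict": {
     "title": "Strict",
     "type": "boolean"
    },
    "threshold": {
     "title": "Threshold",
     "type": "number"
    }
   },
   "required": [
    "n_genes",
    "n_silent",
    "pct_silent",
    "threshold",
    "strict",
    "silent_genes"
   ],
   "title": "SilenceBlock",
   "type": "object"
  }
 },
 "description": "Consolidated audit of a TFome: inventory composition, gene-model\nreconciliation, silence and shift statistics, and paralogy.",
 "properties": {
  "inventory": {
   "$ref": "#/$defs/InventoryBlock"
  },
  "orthology": {
   "anyOf": [
    {
     "$ref": "#/$defs/OrthologyBlock"
    },
    {
     "type": "null"
    }
   ]
  },
  "paralogy": {
   "items": {
    "$ref": "#/$defs/FamilyParalogyBlock"
   },
   "title": "Paralogy",
   "type": "array"
  },
  "reconciliation": {
   "$ref": "#/$defs/ReconciliationBlock"
  },
  "schema_version": {
   "default": "1.0",
   "title": "Schema Version",
   "type": "string"
  },
  "shift": {
   "anyOf": [
    {
     "$ref": "#/$defs/ShiftBlock"
    },
    {
     "type": "null"
    }
   ]
  },
  "silence": {
   "$ref": "#/$defs/SilenceBlock"
  },
  "thresholds": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Thresholds",
   "type": "object"
  }
 },
 "required": [
  "inventory",
  "reconciliation",
  "silence",
  "shift",
  "paralogy",
  "orthology",
  "thresholds"
 ],
 "title": "AuditReport",
 "type": "object"
}
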