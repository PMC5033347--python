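{
  "$defs": {
    "CurveReport": {
      "properties": {
        "degree": {
          "title": "Degree",
          "type": "integer"
        },
        "coefficients": {
          "items": {
            "type": "number"
          },
          "title": "Coefficients",
          "type": "array"
        },
        "p_anova": {
          "title": "P Anova",
          "type": "number"
        },
        "leading_negative": {
          "title": "Leading Negative",
          "type": "boolean"
        },
        "n_derivative_roots": {
          "title": "N Derivative Roots",
          "type": "integer"
        },
        "is_twin_peaks": {
          "title": "Is Twin Peaks",
          "type": "boolean"
        },
        "peaks": {
          "items": {
            "type": "number"
          },
          "title": "Peaks",
          "type": "array"
        },
        "valley": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Valley"
        },
        "permutation_p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Permutation P"
        },
        "n_perm": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "N Perm"
        },
        "bootstrap_pattern_fraction": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bootstrap Pattern Fraction"
        },
        "peak_location_ci": {
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
          "title": "Peak Location Ci"
        }
      },
      "required": [
        "degree",
        "coefficients",
        "p_anova",
        "leading_negative",
        "n_derivative_roots",
        "is_twin_peaks",
        "peaks",
        "valley"
      ],
      "title": "CurveReport",
      "type": "object"
    },
    "QuadraticReport": {
      "properties": {
        "quadratic_coefficient": {
          "title": "Quadratic Coefficient",
          "type": "number"
        },
        "se": {
          "title": "Se",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "fraction_in_window": {
          "title": "Fraction In Window",
          "type": "number"
        },
        "n_in_window": {
          "title": "N In Window",
          "type": "integer"
        }
      },
      "required": [
        "quadratic_coefficient",
        "se",
        "p_value",
        "fraction_in_window",
        "n_in_window"
      ],
      "title": "QuadraticReport",
      "type": "object"
    }
  },
  "description": "Machine-readable run summary; the pydantic model is the schema.",
  "properties": {
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "n_genes": {
      "title": "N Genes",
      "type": "integer"
    },
    "n_rows": {
      "title": "N Rows",
      "type": "integer"
    },
    "filter_report": {
      "additionalProperties": true,
      "title": "Filter Report",
      "type": "object"
    },
    "quartic": {
      "$ref": "#/$defs/CurveReport"
    },
    "quadratic_small_delta": {
      "$ref": "#/$defs/QuadraticReport"
    },
    "het_scaled_quartic": {
      "anyOf": [
        {
          "$ref": "#/$defs/CurveReport"
        },
        {
          "type": "null"
        }
      ]
    },
    "prevalence_fraction": {
      "title": "Prevalence Fraction",
      "type": "number"
    },
    "detected": {
      "title": "Detected",
      "type": "boolean"
    },
    "persnp_fdr_n_significant": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Persnp Fdr N Significant"
    }
  },
  "required": [
    "package_version",
    "seed",
    "n_genes",
    "n_rows",
    "filter_report",
    "quartic",
    "quadratic_small_delta",
    "het_scaled_quartic",
    "prevalence_fraction",
    "detected"
  ],
  "title": "PipelineReport",
  "type": "object"
}
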