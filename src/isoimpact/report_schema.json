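{
  "type": "object",
  "required": ["gene_symbol", "summary", "clusters", "isoforms", "network", "enrichment", "provenance"],
  "properties": {
    "gene_symbol": {"type": "string"},
    "summary": {
      "type": "object",
      "required": ["n_isoforms", "n_clusters", "n_events", "n_de_significant", "n_affected_edges", "n_enriched_terms"],
      "properties": {
        "n_isoforms": {"type": "integer"},
        "n_clusters": {"type": "integer"},
        "n_events": {"type": "integer"},
        "n_de_significant": {"type": "integer"},
        "n_affected_edges": {"type": "integer"},
        "n_enriched_terms": {"type": "integer"}
      }
    },
    "clusters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["cluster_id", "canonical_id", "member_ids"],
        "properties": {
          "cluster_id": {"type": "string"},
          "canonical_id": {"type": "string"},
          "member_ids": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "isoforms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["isoform_id", "cluster_id", "is_canonical", "length", "events", "domain_impacts", "ptm_impacts", "de"],
        "properties": {
          "isoform_id": {"type": "string"},
          "cluster_id": {"type": "string"},
          "is_canonical": {"type": "boolean"},
          "length": {"type": "integer"},
          "events": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["event_type", "canonical_start", "canonical_end", "isoform_start", "isoform_end", "length"],
              "properties": {
                "event_type": {"enum": ["insertion", "deletion", "divergent"]},
                "canonical_start": {"type": "integer"},
                "canonical_end": {"type": "integer"},
                "isoform_start": {"type": ["integer", "null"]},
                "isoform_end": {"type": ["integer", "null"]},
                "length": {"type": "integer"}
              }
            }
          },
          "domain_impacts": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["domain_name", "event_type", "overlap_start", "overlap_end", "overlap_length", "domain_fraction_affected", "insertion_inside"],
              "properties": {
                "domain_name": {"type": "string"},
                "event_type": {"type": "string"},
                "overlap_start": {"type": "integer"},
                "overlap_end": {"type": "integer"},
                "overlap_length": {"type": "integer"},
                "domain_fraction_affected": {"type": "number"},
                "insertion_inside": {"type": "boolean"}
              }
            }
          },
          "ptm_impacts": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["position", "modification_type", "status"],
              "properties": {
                "position": {"type": "integer"},
                "modification_type": {"type": "string"},
                "status": {"enum": ["lost", "altered_context", "retained"]}
              }
            }
          },
          "de": {
            "type": ["array", "null"],
            "items": {
              "type": "object",
              "required": ["tissue", "log2fc", "ppde", "significant", "direction"],
              "properties": {
                "tissue": {"type": "string"},
                "log2fc": {"type": "number"},
                "ppde": {"type": "number"},
                "significant": {"type": "boolean"},
                "direction": {"enum": ["up", "down", "none"]}
              }
            }
          },
          "no_de_data": {"type": "boolean"}
        }
      }
    },
    "network": {
      "type": "object",
      "required": ["disabled", "edges"],
      "properties": {
        "disabled": {"type": "boolean"},
        "canonical_accession": {"type": ["string", "null"]},
        "edges": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["isoform_accession", "partner_id", "interaction_type", "mi_score", "binding_start", "binding_end", "binding_affected", "isoform_specific", "assumed_canonical", "affected_event_indices"],
            "properties": {
              "isoform_accession": {"type": "string"},
              "partner_id": {"type": "string"},
              "interaction_type": {"enum": ["direct", "physical", "association"]},
              "mi_score": {"type": "number"},
              "binding_start": {"type": ["integer", "null"]},
              "binding_end": {"type": ["integer", "null"]},
              "binding_affected": {"type": "boolean"},
              "isoform_specific": {"type": "boolean"},
              "assumed_canonical": {"type": "boolean"},
              "affected_event_indices": {"type": "array", "items": {"type": "integer"}}
            }
          }
        }
      }
    },
    "enrichment": {
      "type": "object",
      "required": ["disabled", "results"],
      "properties": {
        "disabled": {"type": "boolean"},
        "results": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["network_label", "term_id", "term_name", "k", "n", "K", "N", "p_value", "fdr", "overlap_genes"],
            "properties": {
              "network_label": {"type": "string"},
              "term_id": {"type": "string"},
              "term_name": {"type": "string"},
              "k": {"type": "integer"},
              "n": {"type": "integer"},
              "K": {"type": "integer"},
              "N": {"type": "integer"},
              "p_value": {"type": "number"},
              "fdr": {"type": "number"},
              "overlap_genes": {"type": "array", "items": {"type": "string"}}
            }
          }
        }
      }
    },
    "provenance": {
      "type": "object",
      "required": ["tool_version", "parameters", "input_digests", "warnings"],
      "properties": {
        "tool_version": {"type": "string"},
        "parameters": {"type": "object"},
        "input_digests": {"type": "object"},
        "warnings": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
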