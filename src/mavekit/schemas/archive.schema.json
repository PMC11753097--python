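{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mavekit bulk-release archive metadata",
  "description": "Layout of metadata.json in a bulk-release archive directory: structured metadata for every experiment set, experiment and score set. Score and count tables live beside it under tables/ as <urn with ':' replaced by '-'>.scores.csv / .counts.csv.",
  "type": "object",
  "required": ["format_version", "version_tag", "experiment_sets", "experiments", "score_sets"],
  "properties": {
    "format_version": {"type": "integer", "const": 1},
    "version_tag": {"type": "string", "description": "snapshot label, e.g. a release date"},
    "experiment_sets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["urn"],
        "properties": {"urn": {"$ref": "#/$defs/urn"}}
      }
    },
    "experiments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["urn", "experiment_set"],
        "properties": {
          "urn": {"$ref": "#/$defs/urn"},
          "experiment_set": {"$ref": "#/$defs/urn"},
          "title": {"type": "string"},
          "short_description": {"type": "string"},
          "abstract": {"type": "string"},
          "methods": {"type": "string"},
          "references": {"type": "array", "items": {"$ref": "#/$defs/reference"}}
        }
      }
    },
    "score_sets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["urn", "experiment"],
        "properties": {
          "urn": {"$ref": "#/$defs/urn"},
          "experiment": {"$ref": "#/$defs/urn"},
          "title": {"type": "string"},
          "short_description": {"type": "string"},
          "abstract": {"type": "string"},
          "methods": {"type": "string"},
          "target": {
            "oneOf": [
              {"type": "null"},
              {"type": "string", "description": "transcript/genome accession anchor"},
              {
                "type": "object",
                "required": ["label", "kind", "sequence"],
                "properties": {
                  "label": {"type": "string"},
                  "kind": {"enum": ["nucleotide", "protein"]},
                  "sequence": {"type": "string"},
                  "category": {"enum": ["coding", "non_coding", "regulatory", "other"]}
                }
              }
            ]
          },
          "references": {"type": "array", "items": {"$ref": "#/$defs/reference"}},
          "meta_analysis_sources": {
            "type": "array",
            "items": {"$ref": "#/$defs/urn"},
            "description": "nonempty exactly when the record is a meta-analysis score set"
          },
          "has_counts": {"type": "boolean"}
        }
      }
    }
  },
  "$defs": {
    "urn": {
      "type": "string",
      "pattern": "^(urn|tmp):mavedb:[0-9]{8}(-[a-z]+(-[1-9][0-9]*(#[1-9][0-9]*)?)?)?$"
    },
    "reference": {
      "type": "object",
      "required": ["identifier", "source"],
      "properties": {
        "identifier": {"type": "string"},
        "source": {"enum": ["pubmed", "biorxiv", "medrxiv", "crossref_doi"]},
        "is_primary": {"type": "boolean"},
        "journal_or_server": {"type": ["string", "null"]},
        "authors": {"type": "array", "items": {"type": "string"}},
        "year": {"type": ["integer", "null"]}
      }
    }
  }
}
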