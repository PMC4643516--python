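{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.invalid/echotex/terminology.schema.json",
  "title": "echotex terminology file",
  "description": "Structural description of the terminology format accepted by echotex.load_terminology (YAML or JSON by file extension). This document is descriptive: the loader performs its own validation (echotex.validate_terminology) and does not require a JSON-schema validator at runtime. Semantic invariants that a JSON schema cannot express are listed in the x-invariants annotations.",
  "type": "object",
  "required": ["concepts"],
  "additionalProperties": false,
  "properties": {
    "concepts": {
      "description": "Forest of concept nodes; child concepts are contained in their parent (values in attributes, attributes in objects, objects in structures).",
      "type": "array",
      "items": {"$ref": "#/$defs/concept"}
    },
    "templates": {
      "description": "Reusable graded value sets (e.g. a severity scale). A template value matched in text is bound to a concrete attribute at pairing time; its value id is then composed as '<attribute-id>:<local-id>'.",
      "type": "array",
      "items": {"$ref": "#/$defs/template"}
    },
    "dictionaries": {
      "description": "Named shared variant lists referenced by concepts; a concept with a dictionary reference matches every variant of that dictionary in addition to its own.",
      "type": "array",
      "items": {"$ref": "#/$defs/dictionary"}
    },
    "ignore_sections": {
      "description": "Regular expressions (Python re, matched against a line start) opening out-of-domain sections to mask, e.g. transesophageal-echo passages in a transthoracic report.",
      "type": "array",
      "items": {"type": "string"}
    }
  },
  "$defs": {
    "concept": {
      "type": "object",
      "required": ["id", "type"],
      "additionalProperties": false,
      "x-invariants": [
        "ids are globally unique and must not contain ':' (reserved for composed template-value ids)",
        "containment follows the layer order: value < attribute/object_attribute < object < structure",
        "an object_attribute is ambiguous by construction and must be resolvable: it needs at least one candidate object sharing its variant surface or a containing object",
        "boolean_nature: true requires implicit_value naming a value child (or a composable template value) of the same attribute",
        "oa-compound variants are only allowed on attributes and must name an existing object as implied_object",
        "av-compound variants must name an admissible value of the owning attribute as implied_value"
      ],
      "properties": {
        "id": {"type": "string", "pattern": "^[^:]+$"},
        "label": {"type": "string"},
        "type": {"enum": ["structure", "object", "object_attribute", "attribute", "value"]},
        "boolean_nature": {
          "type": "boolean",
          "description": "Attribute states a finding that is present when mentioned at all; the engine then emits an implicit presence pair even without an explicit value."
        },
        "implicit_value": {
          "type": "string",
          "description": "Value id emitted for the implicit presence pair of a boolean_nature attribute."
        },
        "suppress": {
          "type": "boolean",
          "description": "On values only. true (default) marks a passive value that a suppressing value can remove; false marks an activator/negation value (e.g. 'keine Insuffizienz') that suppresses the passive presence value of the same attribute instance."
        },
        "template": {
          "type": "string",
          "description": "Template id whose values are admissible for this attribute (in addition to value children)."
        },
        "dictionaries": {
          "type": "array",
          "items": {"type": "string"},
          "description": "Names of shared variant dictionaries this concept also matches."
        },
        "aspect": {
          "type": "string",
          "description": "Optional label grouping attributes into reporting aspects for per-aspect evaluation."
        },
        "variants": {"type": "array", "items": {"$ref": "#/$defs/variant"}},
        "children": {"type": "array", "items": {"$ref": "#/$defs/concept"}}
      }
    },
    "variant": {
      "description": "A surface form. A bare string is shorthand for a standard variant: token-boundary, case-insensitive (casefolded), Unicode-normalized matching. Regexp variants are matched as written with Python re.",
      "oneOf": [
        {"type": "string"},
        {
          "type": "object",
          "required": ["pattern"],
          "additionalProperties": false,
          "properties": {
            "pattern": {"type": "string"},
            "vtype": {"enum": ["std", "regexp"], "default": "std"},
            "compound": {
              "enum": ["none", "oa", "av"],
              "default": "none",
              "description": "oa: object-attribute compound ('Mitralklappeninsuffizienz') carrying its own disambiguating object; av: attribute-value compound (measurement expression like 'LVEF 60%') carrying its own value."
            },
            "implied_object": {"type": "string", "description": "Object id implied by an oa-compound."},
            "implied_value": {"type": "string", "description": "Value id implied by an av-compound."}
          }
        }
      ]
    },
    "template": {
      "type": "object",
      "required": ["id", "values"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "pattern": "^[^:]+$"},
        "label": {"type": "string"},
        "values": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["id"],
            "additionalProperties": false,
            "properties": {
              "id": {"type": "string", "pattern": "^[^:]+$"},
              "label": {"type": "string"},
              "suppress": {"type": "boolean"},
              "dictionaries": {"type": "array", "items": {"type": "string"}},
              "variants": {"$ref": "#/$defs/variantList"}
            }
          }
        }
      }
    },
    "dictionary": {
      "type": "object",
      "required": ["name", "variants"],
      "additionalProperties": false,
      "properties": {
        "name": {"type": "string"},
        "variants": {"$ref": "#/$defs/variantList"}
      }
    },
    "variantList": {"type": "array", "items": {"$ref": "#/$defs/variant"}}
  }
}
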