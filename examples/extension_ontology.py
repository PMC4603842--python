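"""Emit the chromatin-state extension of the Sequence Ontology.

Six classes (chromatin_region under SO biological_region; chromatin_state
under SO feature_attribute; the four states under chromatin_state) and the
has_state object property, as Turtle.
"""

from nanopubkit import RunConfig, build_extension_ontology, subclass_descendants, write_quads
from nanopubkit.ontology_ext import chromatin_state_class

config = RunConfig()
ext = build_extension_ontology(config)
print(write_quads(ext, "trig"))

root = chromatin_state_class(config)
states = subclass_descendants(ext, root)
print(f"subclass closure beneath chromatin_state: {len(states)} classes")
# Expected: 5 (the state class itself plus active/weak/poised promoter and
# heterochromatic) — the vocabulary the overlap assertions draw from.
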