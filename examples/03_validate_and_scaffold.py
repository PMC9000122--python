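"""Scaffold a mapping template and see the validator's diagnostics.

The scaffold pre-fills one TODO stub per non-key OMOP column.  The
second half introduces a typo to show line-accurate, did-you-mean
diagnostics.
"""

from omopetl import load_catalogue, load_document, scaffold_template

catalogue = load_catalogue("v6")
template = scaffold_template("person", catalogue)
print(template[:400] + "...\n")

doc, diagnostics = load_document(template, "person_scaffold.yaml", catalogue=catalogue)
todos = [d for d in diagnostics if d.code == "TODO_STUB"]
print(f"scaffold parses cleanly with {len(todos)} TODO stubs "
      f"(= the 18 non-key person columns)\n")

broken = template.replace("expression", "experssion", 1)
doc, diagnostics = load_document(broken, "person_scaffold.yaml", catalogue=catalogue)
print("after introducing a typo:")
for d in diagnostics:
    if d.severity == "error":
        print(" ", d.render())
print("# the document is rejected and the nearest keyword is suggested.")
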