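"""Find and render cognition/ADL keyword highlights in a clinical note.

Each lexicon entry is a case-insensitive regex tagged with a category
(cognition or adl) and a polarity (impaired or intact); matches become
character-offset spans that can be rendered as marked-up text.
"""

from natkit import compile_lexicon, default_lexicon, find_spans, render_highlights
from natkit.model import NoteSequence

text = ("Patient seen in follow-up. Family reports memory loss this year. "
        "However, language, attention, and memory function are intact with "
        "good fund of knowledge. Independent in all activities of daily living.")

matcher = compile_lexicon(default_lexicon())
sequence = NoteSequence(note_id="demo", seq_index=0, start=0,
                        end=len(text), text=text)
spans = find_spans(sequence, matcher)

for s in spans:
    print(f"[{s.start:3d},{s.end:3d}) {s.category.value:9s}/"
          f"{s.polarity.value:8s} {text[s.start:s.end]!r}")
print()
print(render_highlights(text, spans))
# Each span reports what the pattern matched and its clinical direction;
# the rendered text wraps spans in <mark> tags keyed by category.
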