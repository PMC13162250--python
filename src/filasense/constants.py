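"""Shared label vocabulary."""

CLASSES = ("blank", "chalk", "pollen", "salt")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
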