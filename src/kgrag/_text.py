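"""Text normalization helpers used by name indexes and the reference embedder."""

import unicodedata


def norm_key(text: str) -> str:
    """NFC-normalize and case-fold a string for case-insensitive matching."""
    return unicodedata.normalize("NFC", text).casefold()
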