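"""Norwegian snowball-style suffix stemmer.

Implements the standard three-step Norwegian stemming algorithm
(suffix stripping in the R1 region, cleanup of -dt/-vt, and removal of
derivational endings).  The algorithm is small enough to carry in-repo,
which keeps the analysis chain — and therefore every golden test value —
stable across environments.

Input is expected to be lowercased; the tokenizer in
:mod:`carefuse.text_index` takes care of that.
"""

from __future__ import annotations

_VOWELS = set("aeiouyæåø")

# Step 1 suffixes, longest first.  -erte/-ertes are replaced by -ert;
# a bare -s is removed only after a "valid s-ending" consonant.
_STEP1 = [
    "hetenes", "hetene", "hetens", "hetes", "heter", "heten",
    "endes", "ertes", "edes", "enes", "erte", "ande", "ende",
    "ane", "ene", "ets", "ers", "ens", "het", "ast", "ede",
    "en", "ar", "er", "as", "es", "et",
    "a", "e", "s",
]

_STEP3 = [
    "hetslov", "slov", "elov", "elig", "eleg",
    "lov", "lig", "leg", "eig", "els", "ig",
]

_S_ENDINGS = set("bcdfghjlmnoprtvyz")


def _r1(word: str) -> int:
    """Start of R1: after the first non-vowel that follows a vowel, ≥ 3."""
    for i in range(1, len(word)):
        if word[i] not in _VOWELS and word[i - 1] in _VOWELS:
            return max(i + 1, 3)
    return len(word)


def stem(word: str) -> str:
    """Stem to a fixed point: the single suffix-stripping pass is applied
    until the word stops changing, so the output is a true normal form
    (idempotent), which the index and query analyzers both rely on."""
    while True:
        out = _stem_once(word)
        if out == word:
            return out
        word = out


def _stem_once(word: str) -> str:
    if len(word) <= 3:
        return word
    p1 = _r1(word)

    # step 1
    for suffix in _STEP1:
        if word.endswith(suffix) and len(word) - len(suffix) >= p1:
            if suffix in ("erte", "ertes"):
                word = word[: -len(suffix)] + "ert"
            elif suffix == "s":
                prev = word[-2]
                if prev in _S_ENDINGS or (
                        prev == "k" and len(word) >= 3
                        and word[-3] not in _VOWELS):
                    word = word[:-1]
            else:
                word = word[: -len(suffix)]
            break

    # step 2: -dt / -vt lose the t
    if len(word) - 1 >= p1 and word.endswith(("dt", "vt")):
        word = word[:-1]

    # step 3
    for suffix in _STEP3:
        if word.endswith(suffix) and len(word) - len(suffix) >= p1:
            word = word[: -len(suffix)]
            break

    return word
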