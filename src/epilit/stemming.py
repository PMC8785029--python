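"""English snowball (Porter2) stemmer.

Dictionary entries and document tokens are stemmed with the same routine so
that inflectional variants of ontology labels ("seizures", "seizure") collapse
to one lookup key ("seizur"). Implemented from the published algorithm
definition: exceptional forms, regions R1/R2, steps 0-5.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDING = frozenset("cdeghkmnrt")

_EXCEPTIONS = {
    "skis": "ski", "skies": "sky", "dying": "die", "lying": "lie",
    "tying": "tie", "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}
# invariant after step 1a
_EXCEPTIONS2 = frozenset(
    {"inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"}
)

_SPECIAL_PREFIXES = ("gener", "commun", "arsen")

_STEP2 = [
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
    ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
    ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"), ("ousli", "ous"),
    ("iviti", "ive"), ("fulli", "ful"), ("enci", "ence"), ("anci", "ance"),
    ("abli", "able"), ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
    ("bli", "ble"), ("ogi", "og"), ("li", ""),
]

_STEP3 = [
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
    ("icate", "ic"), ("iciti", "ic"), ("ative", ""), ("ical", "ic"),
    ("ness", ""), ("ful", ""),
]

_STEP4 = [
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "ion", "al", "er", "ic",
]


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS and word[i] != "Y"


def _regions(word: str) -> tuple[int, int]:
    """Start indices of R1 and R2 (len(word) when the region is empty)."""
    n = len(word)
    r1 = n
    for pre in _SPECIAL_PREFIXES:
        if word.startswith(pre):
            r1 = len(pre)
            break
    else:
        for i in range(1, n):
            if not _is_vowel(word, i) and _is_vowel(word, i - 1):
                r1 = i + 1
                break
    r2 = n
    for i in range(r1 + 1, n):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            r2 = i + 1
            break
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    if n >= 3:
        return (
            not _is_vowel(word, n - 3)
            and _is_vowel(word, n - 2)
            and not _is_vowel(word, n - 1)
            and word[n - 1] not in "wxY"
        )
    return False


def _is_short(word: str, r1: int) -> bool:
    return r1 >= len(word) and _ends_short_syllable(word)


def _has_vowel(segment: str) -> bool:
    return any(ch in _VOWELS and ch != "Y" for ch in segment)


def stem(word: str) -> str:
    """Return the Porter2 stem of a single lowercase word."""
    word = word.lower()
    if len(word) <= 2:
        return word
    if word[0] == "'":
        word = word[1:]
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]

    # mark consonant y
    if word.startswith("y"):
        word = "Y" + word[1:]
    word = "".join(
        "Y" if ch == "y" and i > 0 and _is_vowel(word, i - 1) else ch
        for i, ch in enumerate(word)
    )

    r1, r2 = _regions(word)

    # step 0
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-2] if len(word) > 4 else word[:-1]
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if _has_vowel(word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS2:
        return word

    # step 1b
    found = False
    for suf, repl in (("eedly", "ee"), ("eed", "ee")):
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + repl
            found = True
            break
    if not found:
        for suf in ("ingly", "edly", "ing", "ed"):
            if word.endswith(suf):
                stem_part = word[: -len(suf)]
                if _has_vowel(stem_part):
                    word = stem_part
                    if word.endswith(("at", "bl", "iz")):
                        word += "e"
                    elif word.endswith(_DOUBLES):
                        word = word[:-1]
                    elif _is_short(word, r1):
                        word += "e"
                break

    # step 1c
    if (
        len(word) > 2
        and word[-1] in "yY"
        and not _is_vowel(word, len(word) - 2)
    ):
        word = word[:-1] + "i"

    # step 2 (longest suffix, in R1)
    for suf, repl in _STEP2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "li":
                    if len(word) >= 3 and word[-3] in _LI_ENDING:
                        word = word[:-2]
                elif suf == "ogi":
                    if len(word) >= 4 and word[-4] == "l":
                        word = word[:-1]
                else:
                    word = word[: -len(suf)] + repl
            break

    # step 3 (in R1; 'ative' needs R2)
    for suf, repl in _STEP3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - len(suf) >= r2:
                        word = word[: -len(suf)]
                else:
                    word = word[: -len(suf)] + repl
            break

    # step 4 (longest suffix, in R2)
    for suf in _STEP4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # step 5
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("l") and len(word) - 1 >= r2 and len(word) >= 2 and word[-2] == "l":
        word = word[:-1]

    return word.replace("Y", "y")
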