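"""Independent brute-force mention scanner used as a test oracle.

Deliberately naive: for every (prefix, suffix) phrase pair, every
dictionary name, every separator variant of the name and every character
position, compare string slices directly.  No regular expressions, so it
shares no machinery with the production matcher it checks.
"""

from itertools import product


def _normalize(text: str) -> str:
    return " ".join(text.replace("−", "-").split())


def _name_variants(name: str) -> list[str]:
    """All spellings with each internal space/hyphen swapped either way."""
    norm = _normalize(name)
    slots = []
    parts = []
    cur = ""
    for ch in norm:
        if ch in " -":
            parts.append(cur)
            cur = ""
            slots.append(ch)
        else:
            cur += ch
    parts.append(cur)
    if not slots:
        return [norm]
    variants = []
    for seps in product(" -", repeat=len(slots)):
        s = parts[0]
        for sep, part in zip(seps, parts[1:]):
            s += sep + part
        variants.append(s)
    return variants


def _is_boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and text[start - 1].isalnum():
        return False
    if end < len(text) and text[end].isalnum():
        return False
    return True


def brute_force_mentions(text, entries, phrase_pairs):
    """All (target_id, matched_name, pair_index, start, end) matches.

    ``phrase_pairs`` is a list of (prefix, suffix) strings around the
    target-name slot.  Name matching is case-insensitive for names of 4+
    characters and exact otherwise; fixed phrase words always compare
    case-insensitively.
    """
    t = _normalize(text)
    found = set()
    for pi, (prefix, suffix) in enumerate(phrase_pairs):
        for entry in entries:
            for name in (entry.preferred_name, entry.gene_symbol):
                if not name:
                    continue
                for variant in _name_variants(name):
                    total = len(prefix) + len(variant) + len(suffix)
                    for i in range(len(t) - total + 1):
                        seg_pre = t[i : i + len(prefix)]
                        seg_name = t[i + len(prefix) : i + len(prefix) + len(variant)]
                        seg_suf = t[i + len(prefix) + len(variant) : i + total]
                        if seg_pre.lower() != prefix.lower():
                            continue
                        if seg_suf.lower() != suffix.lower():
                            continue
                        if len(name) >= 4:
                            if seg_name.lower() != variant.lower():
                                continue
                        elif seg_name != variant:
                            continue
                        if not _is_boundary_ok(t, i, i + total):
                            continue
                        found.add((entry.target_id, name, pi, i, i + total))
    return found
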