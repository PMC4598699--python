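"""Published single-milking prediction equations and their text grammar.

Model forms are written the way milk-recording reports print them, e.g.::

    a + b x (qFAT_AM x milk_AM x DIM) + c x (parity) + d x (milk_AM x parity)

``a`` is the intercept and each later letter a regression coefficient
(estimated separately per occupied subclass cell when class factors are
present).  Factors inside a term: ``milk_AM``/``milk_PM`` is the session
milk yield (kg); ``q<TRAIT>_<SESSION>`` the session content (g/dL) of the
modelled trait; ``DIM``, ``parity`` and ``month of test`` are class
factors.  ``parse_model`` turns such a string into a
:class:`~ampmyield.modelfit.ModelSpec`; ``format_model`` renders one back.

``PRESET_MODELS`` ships the externally selected best-fit equation for each
of the nine traits and both milking sessions (18 models), so the forms can
be fitted directly without re-running stepwise selection.
"""

from __future__ import annotations

import re
import string

from .modelfit import ModelSpec, Term
from .traits import ALL_TRAITS

__all__ = ["parse_model", "format_model", "PRESET_MODELS", "preset_model"]

_TRAIT_TOKEN = {
    "fat": "FAT", "sfa": "SFA", "mufa": "MUFA", "ufa": "UFA",
    "scfa": "SCFA", "mcfa": "MCFA", "lcfa": "LCFA",
    "c18_1_cis9": "C18:1cis9", "milk": "MILK",
}


def _parse_factor(token: str, trait: str, session: str):
    t = re.sub(r"\s+", " ", token.strip()).lower()
    if t in ("dim", "cdim"):
        return ("class", "dim")
    if t == "parity":
        return ("class", "parity")
    if t in ("month", "month of test"):
        return ("class", "month")
    if t.startswith("milk"):
        m = re.fullmatch(r"milk(?:_(am|pm))?", t)
        if m is None:
            raise ValueError(f"cannot parse milk factor {token!r}")
        if m.group(1) and m.group(1) != session:
            raise ValueError(
                f"factor {token!r} names session {m.group(1)!r} but the model "
                f"is for session {session!r}"
            )
        return ("cov", "milk")
    if t.startswith("q"):
        m = re.fullmatch(r"q(.+?)(?:_(am|pm))?", t)
        if m.group(2) and m.group(2) != session:
            raise ValueError(
                f"factor {token!r} names session {m.group(2)!r} but the model "
                f"is for session {session!r}"
            )
        named = re.sub(r"[\s:_-]", "", m.group(1)).lower()
        expected = re.sub(r"[\s:_-]", "", _TRAIT_TOKEN[trait]).lower()
        if named != expected:
            raise ValueError(
                f"content factor {token!r} does not match model trait {trait!r}"
            )
        return ("cov", "q")
    raise ValueError(f"unknown model factor {token!r}")


def parse_model(text: str, trait: str, session: str) -> ModelSpec:
    """Parse a printed model form into a :class:`ModelSpec`.

    The leading intercept letter and per-term coefficient letters are
    ignored; parentheses are optional.  Factor separators may be ``x``
    (surrounded by spaces), ``*`` or the multiplication sign.
    """
    if trait not in ALL_TRAITS:
        raise KeyError(f"unknown trait {trait!r}")
    body = text.replace("×", "*")
    body = re.sub(r"(?<=[\s)\w])\s+x\s+", " * ", body)
    terms: list[Term] = []
    for raw in body.split("+"):
        chunk = raw.strip()
        if not chunk:
            continue
        # strip a leading single coefficient letter followed by '*'
        m = re.match(r"^[a-z]\s*\*\s*(.+)$", chunk)
        if m:
            chunk = m.group(1).strip()
        elif re.fullmatch(r"[a-z]", chunk):
            continue  # bare intercept letter
        chunk = chunk.strip()
        if chunk.startswith("(") and chunk.endswith(")"):
            chunk = chunk[1:-1]
        covs, clss = [], []
        for token in chunk.split("*"):
            kind, name = _parse_factor(token, trait, session)
            (covs if kind == "cov" else clss).append(name)
        terms.append(Term(covariates=tuple(covs), classes=tuple(clss)))
    return ModelSpec(trait=trait, session=session, terms=tuple(terms))


def format_model(spec: ModelSpec) -> str:
    """Render a spec in the printed equation style (``a + b x (...) + ...``)."""
    letters = string.ascii_lowercase
    parts = ["a"]
    for i, term in enumerate(spec.terms):
        lab = term.label(spec.trait, spec.session)
        parts.append(f"{letters[i + 1]} x ({lab})")
    return " + ".join(parts)


_PRESET_TEXT: dict[tuple[str, str], str] = {
    ("milk", "am"): "a + b x DIM + c x month of test + d x (milk_AM x DIM x parity x month of test)",
    ("milk", "pm"): "a + b x DIM + c x month of test + d x (milk_PM x DIM x parity x month of test)",
    ("fat", "am"): "a + b x (qFAT_AM x milk_AM x DIM) + c x (parity) + d x (milk_AM x parity) + e x (qFAT_AM x milk_AM x parity)",
    ("fat", "pm"): "a + b x (milk_PM x DIM) + c x (qFAT_PM x milk_PM x DIM) + d x parity + e x (qFAT_PM x milk_PM x month of test)",
    ("sfa", "am"): "a + b x (qSFA_AM x milk_AM x DIM) + c x parity + d x (milk_AM x parity) + e x (milk_AM x month of test)",
    ("sfa", "pm"): "a + b x (milk_PM x DIM) + c x (qSFA_PM x milk_PM x DIM) + d x (parity) + e x month of test",
    ("mufa", "am"): "a + b x (milk_AM x DIM) + c x (milk_AM x parity) + d x (qMUFA_AM x milk_AM x DIM x parity) + e x (qMUFA_AM x milk_AM x month of test)",
    ("mufa", "pm"): "a + b x (milk_PM x DIM) + c x parity + d x (qMUFA_PM x milk_PM x DIM x parity) + e x (milk_PM x month of test)",
    ("ufa", "am"): "a + b x (milk_AM x DIM) + c x (qUFA_AM x milk_AM x DIM) + d x parity + e x (milk_AM x parity)",
    ("ufa", "pm"): "a + b x (milk_PM x DIM) + c x (qUFA_PM x milk_PM x DIM x parity) + d x (milk_PM x month of test) + e x (qUFA_PM x DIM x parity x month of test)",
    ("scfa", "am"): "a + b x (qSCFA_AM x milk_AM x DIM) + c x parity + d x (milk_AM x parity) + e x month of test",
    ("scfa", "pm"): "a + b x (qSCFA_PM x milk_PM x DIM) + c x (milk_PM x parity) + d x (milk_PM x month of test) + e x (qSCFA_PM x DIM x parity x month of test)",
    ("mcfa", "am"): "a + b x (qMCFA_AM x milk_AM x DIM) + c x parity + d x (qMCFA_AM x milk_AM x month of test) + e x (qMCFA_AM x DIM x parity x month of test)",
    ("mcfa", "pm"): "a + b x (milk_PM x DIM) + c x (qMCFA_PM x milk_PM x DIM) + d x (milk_PM x parity) + e x month of test + f x (qMCFA_PM x DIM x parity x month of test)",
    ("lcfa", "am"): "a + b x (milk_AM x DIM x parity) + c x (qLCFA_AM x milk_AM x DIM x parity) + d x (milk_AM x month of test) + e x (qLCFA_AM x milk_AM x month of test) + f x (qLCFA_AM x DIM x parity x month of test)",
    ("lcfa", "pm"): "a + b x (milk_PM x DIM) + c x (qLCFA_PM x milk_PM x DIM x parity) + d x (milk_PM x parity x month of test) + e x (qLCFA_PM x DIM x parity x month of test)",
    ("c18_1_cis9", "am"): "a + b x (milk_AM x DIM) + c x (milk_AM x parity) + d x (qC18:1cis9_AM x milk_AM x DIM x parity) + e x (qC18:1cis9_AM x milk_AM x parity x month of test) + f x (qC18:1cis9_AM x DIM x parity x month of test)",
    ("c18_1_cis9", "pm"): "a + b x (milk_PM x DIM) + c x (qC18:1cis9_PM x milk_PM x DIM x parity) + d x month of test + e x (qC18:1cis9_PM x milk_PM x month of test) + f x (qC18:1cis9_PM x DIM x parity x month of test)",
}

#: the selected best-fit model form per (trait, session)
PRESET_MODELS: dict[tuple[str, str], ModelSpec] = {
    key: parse_model(text, *key) for key, text in _PRESET_TEXT.items()
}


def preset_model(trait: str, session: str) -> ModelSpec:
    """The shipped best-fit equation for one trait and milking session."""
    try:
        return PRESET_MODELS[(trait, session)]
    except KeyError:
        raise KeyError(
            f"no preset model for trait {trait!r}, session {session!r}"
        ) from None
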