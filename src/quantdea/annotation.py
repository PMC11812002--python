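"""Sample annotation parsing and the contrast specification language.

The annotation table drives the whole analysis: its first column holds the
sample identifier exactly as the quantification software spells it, further
columns assign a short display name, the group (the single explanatory
factor), an optional subject/blocking factor, and either

* a ``control`` column marking the reference condition (``C``) — every other
  group is then compared against it, or
* explicit ``ContrastName`` / ``Contrast`` columns, where each contrast is an
  arithmetic expression over ``G_``-prefixed group identifiers and previously
  defined contrast names, e.g. ``(G_T_Old + G_T_Young)/2 - (G_NAT_Old +
  G_NAT_Young)/2``.

Expressions are compiled to linear coefficient vectors over the group means;
a contrast may reference earlier contrasts (contrasts of contrasts), which
substitutes their coefficient vectors.
"""

from __future__ import annotations

import ast
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: case-insensitive aliases for each annotation role
SAMPLE_ALIASES = ("relative.path", "path", "raw.file", "channel")
NAME_ALIASES = ("name",)
GROUP_ALIASES = ("group", "experiment")
SUBJECT_ALIASES = ("subject", "bioreplicate")
CONTROL_ALIASES = ("control",)
CONTRAST_NAME_ALIASES = ("contrastname",)
CONTRAST_ALIASES = ("contrast",)


class AnnotationError(ValueError):
    pass


class ContrastError(ValueError):
    pass


@dataclass
class SampleAnnotation:
    """Parsed experimental design: sample -> (name, group, subject)."""

    table: pd.DataFrame  # columns: sample_id, name, group, [subject], [control]
    has_subject: bool = False
    has_control: bool = False
    contrast_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def subject_of(self) -> pd.Series | None:
        if not self.has_subject:
            return None
        return self.table.set_index("sample_id")["subject"]

    def rename_samples(self, mapping: dict[str, str]) -> "SampleAnnotation":
        """Replace annotation sample ids by their matched data-side ids."""
        tab = self.table.copy()
        tab["sample_id"] = tab["sample_id"].map(lambda s: mapping.get(s, s))
        return SampleAnnotation(tab, self.has_subject, self.has_control, list(self.contrast_rows))


@dataclass(frozen=True)
class ContrastVector:
    """A named linear combination of group means."""

    name: str
    coefficients: dict[str, float]  # raw group level -> coefficient

    def __post_init__(self):
        if not any(abs(c) > 0 for c in self.coefficients.values()):
            raise ContrastError(f"contrast {self.name!r} has all-zero coefficients")

    def nonzero_groups(self) -> list[str]:
        return [g for g, c in self.coefficients.items() if abs(c) > 0]


@dataclass
class ContrastSet:
    contrasts: list[ContrastVector] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name for c in self.contrasts]
        if len(names) != len(set(names)):
            raise ContrastError(f"duplicate contrast names: {names}")

    def __iter__(self):
        return iter(self.contrasts)

    def __len__(self):
        return len(self.contrasts)

    def names(self) -> list[str]:
        return [c.name for c in self.contrasts]

    def get(self, name: str) -> ContrastVector:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise KeyError(name)


# ---------------------------------------------------------------------------
# annotation parsing


def _read_annotation_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def _find_alias(columns: list[str], aliases: tuple[str, ...]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def parse_annotation(path: str | Path) -> SampleAnnotation:
    """Read the annotation XLSX/TSV and resolve column aliases case-insensitively."""
    raw = _read_annotation_frame(path)
    cols = list(raw.columns)
    sample_col = _find_alias(cols, SAMPLE_ALIASES)
    if sample_col is None:
        # fall back: the first column is reserved for the sample identifier
        sample_col = cols[0]
        logger.warning(
            "no sample-id alias %s found; using first column %r", SAMPLE_ALIASES, sample_col
        )
    group_col = _find_alias(cols, GROUP_ALIASES)
    if group_col is None:
        raise AnnotationError(f"no group column found (aliases: {GROUP_ALIASES})")
    name_col = _find_alias(cols, NAME_ALIASES)
    subject_col = _find_alias(cols, SUBJECT_ALIASES)
    control_col = _find_alias(cols, CONTROL_ALIASES)
    cn_col = _find_alias(cols, CONTRAST_NAME_ALIASES)
    c_col = _find_alias(cols, CONTRAST_ALIASES)

    def clean(s: pd.Series) -> pd.Series:
        return s.astype("string").str.strip()

    tab = pd.DataFrame({"sample_id": clean(raw[sample_col])})
    tab["name"] = clean(raw[name_col]) if name_col else tab["sample_id"]
    tab["group"] = clean(raw[group_col])
    if subject_col is not None:
        tab["subject"] = clean(raw[subject_col])
    if control_col is not None:
        tab["control"] = clean(raw[control_col]).str.upper()

    tab = tab[tab["sample_id"].notna() & (tab["sample_id"] != "")].reset_index(drop=True)
    dup = tab["sample_id"].duplicated()
    if dup.any():
        raise AnnotationError(
            f"duplicate sample identifiers: {sorted(tab['sample_id'][dup].unique())}"
        )
    if tab["group"].isna().any() or (tab["group"] == "").any():
        bad = tab.loc[tab["group"].isna() | (tab["group"] == ""), "sample_id"]
        raise AnnotationError(f"empty group for samples: {list(bad)}")

    has_control = control_col is not None and tab.get("control") is not None and (
        tab["control"].fillna("") != ""
    ).any()
    contrast_rows: list[tuple[str, str]] = []
    if cn_col is not None and c_col is not None:
        names = clean(raw[cn_col]).fillna("")
        exprs = clean(raw[c_col]).fillna("")
        for n, e in zip(names, exprs):
            if n and e:
                contrast_rows.append((str(n), str(e)))
    elif (cn_col is None) != (c_col is None):
        raise AnnotationError("ContrastName and Contrast columns must appear together")

    if has_control and contrast_rows:
        raise AnnotationError(
            "annotation mixes design modes: use either a control column "
            "or ContrastName/Contrast columns, not both"
        )
    if not has_control and not contrast_rows:
        raise AnnotationError(
            "no design found: add a 'control' column marking the reference group with C, "
            "or 'ContrastName'/'Contrast' columns specifying the comparisons"
        )
    return SampleAnnotation(
        table=tab,
        has_subject=subject_col is not None,
        has_control=has_control,
        contrast_rows=contrast_rows,
    )


def make_annotation_template(sample_ids: list[str], out: str | Path, tsv: bool = False) -> Path:
    """Write an annotation skeleton with the sample ids pre-filled."""
    out = Path(out)
    if not sample_ids:
        logger.warning("no sample identifiers found; writing header-only template")
    df = pd.DataFrame(
        {
            "raw.file": list(sample_ids),
            "name": [""] * len(sample_ids),
            "group": [""] * len(sample_ids),
            "subject": [""] * len(sample_ids),
            "control": [""] * len(sample_ids),
        }
    )
    if tsv or out.suffix.lower() in {".tsv", ".txt"}:
        df.to_csv(out, sep="\t", index=False)
    else:
        df.to_excel(out, index=False)
    return out


# ---------------------------------------------------------------------------
# group-level sanitization and contrast compilation

_GROUP_PREFIX = "G_"


def sanitize_group_levels(levels: list[str]) -> dict[str, str]:
    """Map each raw group level to its ``G_``-prefixed identifier.

    Non-alphanumeric characters become ``_``; the mapping must be injective.
    """
    if not levels:
        raise ContrastError("no group levels to sanitize")
    mapping = {lvl: _GROUP_PREFIX + re.sub(r"[^0-9A-Za-z]", "_", str(lvl)) for lvl in levels}
    seen: dict[str, str] = {}
    for raw, ident in mapping.items():
        if ident in seen:
            raise ContrastError(
                f"group levels {seen[ident]!r} and {raw!r} both sanitize to {ident!r}; "
                "rename one of them"
            )
        seen[ident] = raw
    return mapping


def contrasts_from_control(annotation: SampleAnnotation) -> ContrastSet:
    """Expand the control-column design: each group vs the control group."""
    if "control" not in annotation.table.columns:
        raise ContrastError("annotation has no control column")
    tab = annotation.table
    marked = tab.loc[tab["control"].fillna("") == "C", "group"].unique()
    if len(marked) == 0:
        raise ContrastError("no group is marked as control (C)")
    if len(marked) > 1:
        raise ContrastError(f"control marker C appears in multiple groups: {sorted(marked)}")
    control = marked[0]
    groups = [g for g in annotation.groups if g != control]
    if not groups:
        raise ContrastError("only the control group is present; nothing to compare")
    vectors = [
        ContrastVector(
            name=f"{g}_vs_{control}",
            coefficients={lvl: (1.0 if lvl == g else -1.0 if lvl == control else 0.0)
                          for lvl in annotation.groups},
        )
        for g in groups
    ]
    return ContrastSet(vectors)


class _LinearExpr:
    """Linear form over identifiers: coefficients + constant."""

    __slots__ = ("coef", "const")

    def __init__(self, coef=None, const=0.0):
        self.coef = dict(coef or {})
        self.const = float(const)

    def scaled(self, k: float) -> "_LinearExpr":
        return _LinearExpr({n: k * c for n, c in self.coef.items()}, k * self.const)

    def plus(self, other: "_LinearExpr") -> "_LinearExpr":
        coef = dict(self.coef)
        for n, c in other.coef.items():
            coef[n] = coef.get(n, 0.0) + c
        return _LinearExpr(coef, self.const + other.const)

    @property
    def is_constant(self) -> bool:
        return all(c == 0 for c in self.coef.values())


def _eval_linear(node: ast.expr, resolve) -> _LinearExpr:
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ContrastError(f"unsupported literal {node.value!r}")
        return _LinearExpr(const=node.value)
    if isinstance(node, ast.Name):
        return _LinearExpr(coef=resolve(node.id))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.UAdd, ast.USub)):
        inner = _eval_linear(node.operand, resolve)
        return inner if isinstance(node.op, ast.UAdd) else inner.scaled(-1.0)
    if isinstance(node, ast.BinOp):
        if isinstance(node.op, ast.Add):
            return _eval_linear(node.left, resolve).plus(_eval_linear(node.right, resolve))
        if isinstance(node.op, ast.Sub):
            return _eval_linear(node.left, resolve).plus(
                _eval_linear(node.right, resolve).scaled(-1.0)
            )
        if isinstance(node.op, ast.Mult):
            left = _eval_linear(node.left, resolve)
            right = _eval_linear(node.right, resolve)
            if left.is_constant:
                return right.scaled(left.const)
            if right.is_constant:
                return left.scaled(right.const)
            raise ContrastError("nonlinear contrast: product of two group terms")
        if isinstance(node.op, ast.Div):
            left = _eval_linear(node.left, resolve)
            right = _eval_linear(node.right, resolve)
            if not right.is_constant:
                raise ContrastError("division by a group term is not linear")
            if right.const == 0:
                raise ContrastError("division by zero in contrast expression")
            return left.scaled(1.0 / right.const)
    raise ContrastError(f"unsupported syntax in contrast expression: {ast.dump(node)}")


def parse_contrast_expression(
    name: str,
    expr: str,
    known: ContrastSet | None,
    groups: list[str],
) -> ContrastVector:
    """Compile an arithmetic contrast expression to a coefficient vector.

    Identifiers resolve to ``G_``-prefixed group levels or to the names of
    previously defined contrasts (whose vectors are substituted — this is what
    makes contrasts-of-contrasts like an interaction difference work).
    """
    sanitized = sanitize_group_levels(groups)
    ident_to_level = {ident: lvl for lvl, ident in sanitized.items()}
    known_by_name = {c.name: c for c in (known or [])}

    def resolve(ident: str) -> dict[str, float]:
        if ident in ident_to_level:
            return {ident_to_level[ident]: 1.0}
        if ident in known_by_name:
            return dict(known_by_name[ident].coefficients)
        raise ContrastError(
            f"unknown identifier {ident!r} in contrast {name!r}; "
            f"known groups: {sorted(ident_to_level)}; "
            f"known contrasts: {sorted(known_by_name)}"
        )

    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ContrastError(f"cannot parse contrast {name!r}: {exc}") from exc
    lin = _eval_linear(tree.body, resolve)
    if abs(lin.const) > 1e-12:
        raise ContrastError(
            f"contrast {name!r} has a nonzero constant term ({lin.const}); "
            "contrasts must be combinations of group means"
        )
    coefficients = {lvl: float(lin.coef.get(lvl, 0.0)) for lvl in groups}
    return ContrastVector(name=name, coefficients=coefficients)


def compile_contrasts(annotation: SampleAnnotation) -> ContrastSet:
    """Build the full ContrastSet from either design mode of the annotation."""
    if annotation.has_control:
        return contrasts_from_control(annotation)
    contrasts: list[ContrastVector] = []
    for name, expr in annotation.contrast_rows:
        vec = parse_contrast_expression(name, expr, ContrastSet(list(contrasts)), annotation.groups)
        contrasts.append(vec)
    if not contrasts:
        raise ContrastError("no contrasts defined")
    return ContrastSet(contrasts)


# ---------------------------------------------------------------------------
# sample-id matching


def _normalize_id(s: str) -> str:
    base = re.split(r"[/\\]", s)[-1]
    return re.sub(r"\.[^.]*$", "", base)


def match_sample_ids(annotation_ids: list[str], data_ids: list[str]) -> dict[str, str]:
    """Match annotation sample ids to data sample ids.

    Exact string matches win; remaining ids are retried after stripping
    directory components and the final extension on both sides (quantification
    tools disagree on whether paths/extensions are kept).  The mapping must be
    injective; ambiguity is fatal.
    """
    if not annotation_ids or not data_ids:
        raise AnnotationError("cannot match empty sample-id lists")
    data_set = set(data_ids)
    mapping: dict[str, str] = {}
    unmatched = []
    for a in annotation_ids:
        if a in data_set:
            mapping[a] = a
        else:
            unmatched.append(a)
    used = set(mapping.values())
    if unmatched:
        norm_data: dict[str, list[str]] = {}
        for d in data_ids:
            if d in used:
                continue
            norm_data.setdefault(_normalize_id(d), []).append(d)
        still = []
        for a in unmatched:
            cands = norm_data.get(_normalize_id(a), [])
            if len(cands) > 1:
                raise AnnotationError(
                    f"annotation sample {a!r} ambiguously matches data samples {cands}"
                )
            if len(cands) == 1:
                mapping[a] = cands[0]
                used.add(cands[0])
            else:
                still.append(a)
        if still:
            raise AnnotationError(
                f"annotation samples not found in data (after normalization): {still}; "
                f"data samples: {sorted(data_set)}"
            )
    if len(set(mapping.values())) != len(mapping):
        raise AnnotationError("sample-id matching is not injective")
    return mapping
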