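"""Multiple sequence alignments: I/O, recoding, site filtering, compositions.

The central container is :class:`Alignment`, a taxa-by-sites character
matrix over a declared :class:`~hetphylo.alphabets.Alphabet`.  Reading
upper-cases characters and maps nucleotide ``U`` to ``T``; every
character must belong to the alphabet, its ambiguity codes, or the
missing set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AA, BIN, DAY6, DNA, Alphabet, get_alphabet
from .errors import CharacterError, FormatError, LabelError, UsageError

__all__ = [
    "Alignment",
    "CompositionTable",
    "read_alignment",
    "write_alignment",
    "recode",
    "filter_sites",
    "remove_constant_proportion",
    "remove_fastest_n",
    "mask_sites",
    "constant_columns",
    "composition_counts",
]

# Dayhoff groups of chemically related amino acids
DAYHOFF6_GROUPS = {
    "AGPST": "1", "C": "2", "DENQ": "3", "FWY": "4", "HKR": "5", "ILMV": "6",
}


@dataclass
class Alignment:
    """An alignment of ``n_taxa`` rows by ``n_sites`` columns.

    ``matrix`` is a 2-D numpy array of single characters; rows follow
    ``labels``.  Invariants (unique labels, rectangular matrix, legal
    characters) are enforced at construction.
    """

    labels: list
    matrix: np.ndarray
    alphabet: Alphabet

    def __post_init__(self):
        self.alphabet = get_alphabet(self.alphabet)
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise FormatError("alignment matrix must be 2-D with at least 1 column")
        if len(self.labels) != self.matrix.shape[0]:
            raise FormatError("label count does not match matrix rows")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise LabelError(f"duplicate taxon labels: {dup}")
        self._validate_chars()

    def _validate_chars(self):
        ok = np.zeros(self.matrix.shape, dtype=bool)
        for ch in set(self.matrix.ravel().tolist()):
            if self.alphabet.is_valid(ch):
                ok |= self.matrix == ch
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise CharacterError(self.labels[i], int(j), str(self.matrix[i, j]))

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, label: str) -> str:
        return "".join(self.matrix[self.labels.index(label)])

    def take_sites(self, index) -> "Alignment":
        return Alignment(list(self.labels), self.matrix[:, index], self.alphabet)

    def take_taxa(self, labels) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(list(labels), self.matrix[idx], self.alphabet)

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.alphabet.name == other.alphabet.name
            and np.array_equal(self.matrix, other.matrix)
        )


def _clean(seq: str, alphabet: Alphabet) -> str:
    s = seq.upper().replace(" ", "")
    if alphabet.name == "DNA":
        s = s.replace("U", "T")
    return s


def _from_pairs(pairs, alphabet: Alphabet) -> Alignment:
    labels = [p[0] for p in pairs]
    seqs = [_clean(p[1], alphabet) for p in pairs]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
    matrix = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(labels, matrix, alphabet)


def _read_phylip(handle, alphabet: Alphabet):
    """Relaxed sequential PHYLIP: names up to 250 chars ended by whitespace."""
    header = handle.readline().split()
    if len(header) < 2:
        raise FormatError("PHYLIP header must give taxon and site counts")
    try:
        n_taxa, n_sites = int(header[0]), int(header[1])
    except ValueError:
        raise FormatError(f"bad PHYLIP header: {' '.join(header)!r}")
    pairs = []
    name, chunks, have = None, [], 0
    for raw in handle:
        line = raw.strip()
        if not line:
            continue
        if name is None:
            parts = line.split(None, 1)
            name = parts[0]
            if len(name) > 250:
                raise FormatError(f"taxon name longer than 250 characters: {name[:30]}...")
            rest = parts[1] if len(parts) > 1 else ""
            chunks, have = [rest], len(rest.replace(" ", ""))
        else:
            chunks.append(line)
            have += len(line.replace(" ", ""))
        if have >= n_sites:
            pairs.append((name, "".join(chunks)))
            name = None
    if name is not None or len(pairs) != n_taxa:
        raise FormatError(
            f"PHYLIP header declared {n_taxa} taxa of {n_sites} sites; "
            f"parsed {len(pairs)} complete rows"
        )
    for _, s in pairs:
        if len(s.replace(" ", "")) != n_sites:
            raise FormatError("PHYLIP row length does not match header")
    return pairs


def read_alignment(path, format: str, alphabet) -> Alignment:
    """Read a FASTA or (relaxed sequential) PHYLIP alignment."""
    alphabet = get_alphabet(alphabet)
    if format == "fasta":
        with open(path) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
        if not records:
            raise FormatError(f"no FASTA records in {path}")
        pairs = [(r.id, str(r.seq)) for r in records]
        return _from_pairs(pairs, alphabet)
    if format == "phylip":
        with open(path) as fh:
            pairs = _read_phylip(fh, alphabet)
        return _from_pairs(pairs, alphabet)
    raise UsageError(f"unknown alignment format {format!r}")


def write_alignment(a: Alignment, path, format: str) -> None:
    rows = ["".join(r) for r in a.matrix]
    if format == "fasta":
        records = [
            SeqRecord(Seq(s), id=l, description="") for l, s in zip(a.labels, rows)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{a.n_taxa} {a.n_sites}\n")
            for l, s in zip(a.labels, rows):
                fh.write(f"{l}  {s}\n")
    else:
        raise UsageError(f"unknown alignment format {format!r}")


def loads(text: str, format: str, alphabet) -> Alignment:
    """Parse an alignment from a string (convenience for small fixtures)."""
    alphabet = get_alphabet(alphabet)
    if format == "fasta":
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise FormatError("no FASTA records")
        return _from_pairs([(r.id, str(r.seq)) for r in records], alphabet)
    if format == "phylip":
        return _from_pairs(_read_phylip(io.StringIO(text), alphabet), alphabet)
    raise UsageError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# recoding

def _ry_map():
    m = {"A": "R", "G": "R", "R": "R", "C": "Y", "T": "Y", "Y": "Y"}
    return m


def _dayhoff_map():
    m = {}
    for group, target in DAYHOFF6_GROUPS.items():
        for ch in group:
            m[ch] = target
    return m


def recode(a: Alignment, scheme, custom_map=None, target_alphabet=None) -> Alignment:
    """Collapse an alignment onto a smaller alphabet.

    ``RY`` (DNA only) maps purines A,G to R and pyrimidines C,T to Y;
    ``dayhoff6`` (amino acids only) maps each residue to its Dayhoff
    group.  Ambiguity codes map to the shared group where one exists
    (e.g. amino-acid B, spanning N and D, both group 3) and to ``?``
    otherwise.  Missing symbols pass through unchanged.
    """
    if scheme == "RY":
        if a.alphabet.name != "DNA":
            raise UsageError("RY recoding applies to DNA alignments only")
        plain_map, target = _ry_map(), BIN
    elif scheme == "dayhoff6":
        if a.alphabet.name != "AA":
            raise UsageError("dayhoff6 recoding applies to amino-acid alignments only")
        plain_map, target = _dayhoff_map(), DAY6
    elif scheme == "custom":
        if custom_map is None or target_alphabet is None:
            raise UsageError("custom recoding needs custom_map and target_alphabet")
        target = get_alphabet(target_alphabet)
        missing_targets = set(custom_map.values()) - set(target.states)
        if missing_targets:
            raise UsageError(f"custom map targets outside alphabet: {missing_targets}")
        if set(custom_map) != set(a.alphabet.states):
            raise UsageError("custom map must cover every source state")
        if set(custom_map.values()) != set(target.states):
            raise UsageError("custom map must be onto the target alphabet")
        plain_map = dict(custom_map)
    else:
        raise UsageError(f"unknown recoding scheme {scheme!r}")

    full = dict(plain_map)
    for ch, states in a.alphabet.ambiguity.items():
        if ch in full:
            continue
        images = {plain_map.get(s) for s in states}
        full[ch] = images.pop() if len(images) == 1 and None not in images else "?"
    for ch in a.alphabet.missing:
        full.setdefault(ch, ch)

    out = np.empty_like(a.matrix)
    for ch in set(a.matrix.ravel().tolist()):
        out[a.matrix == ch] = full.get(ch, "?")
    return Alignment(list(a.labels), out, target)


# ---------------------------------------------------------------------------
# site filtering

def _missing_mask(a: Alignment) -> np.ndarray:
    """True where a character carries no definite single state."""
    mask = np.zeros(a.matrix.shape, dtype=bool)
    for ch in set(a.matrix.ravel().tolist()):
        if a.alphabet.is_missing(ch) or a.alphabet.is_ambiguous(ch):
            mask |= a.matrix == ch
    return mask


def constant_columns(a: Alignment):
    """(column indices, constant state) for columns whose non-missing
    characters are all identical, with at least one non-missing character."""
    miss = _missing_mask(a)
    cols, states = [], []
    for j in range(a.n_sites):
        vals = a.matrix[~miss[:, j], j]
        if vals.size and (vals == vals[0]).all():
            cols.append(j)
            states.append(str(vals[0]))
    return np.array(cols, dtype=int), states


def remove_constant_proportion(a: Alignment, p: float) -> Alignment:
    """Remove ``floor(p * n_constant)`` constant columns.

    Removals are allocated across constant-state classes proportionally
    to class frequency by largest-remainder rounding (ties broken toward
    the larger quota, then alphabet order); within a class the
    lowest-index columns are removed.
    """
    if not 0 <= p <= 1:
        raise UsageError(f"p must be in [0, 1], got {p}")
    if p == 0:
        return a
    cols, states = constant_columns(a)
    n_const = len(cols)
    n_remove = int(np.floor(p * n_const))
    if n_remove == 0:
        return a
    order = list(a.alphabet.states) + sorted(set(states) - set(a.alphabet.states))
    classes = [s for s in order if s in states]
    counts = {s: states.count(s) for s in classes}
    quota = {s: n_remove * counts[s] / n_const for s in classes}
    take = {s: int(np.floor(quota[s])) for s in classes}
    seats = n_remove - sum(take.values())
    by_remainder = sorted(
        classes, key=lambda s: (-(quota[s] - take[s]), -quota[s], order.index(s))
    )
    for s in by_remainder[:seats]:
        take[s] += 1
    drop = []
    for s in classes:
        members = [c for c, st in zip(cols, states) if st == s]
        drop.extend(members[: min(take[s], counts[s])])
    keep = np.setdiff1d(np.arange(a.n_sites), np.array(drop, dtype=int))
    return a.take_sites(keep)


def remove_fastest_n(a: Alignment, n: int, rates) -> Alignment:
    """Remove the n columns with the highest rate (ties: lower index first)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (a.n_sites,):
        raise UsageError("rates must have one entry per alignment column")
    if not 0 <= n <= a.n_sites:
        raise UsageError(f"n must be in [0, {a.n_sites}], got {n}")
    # stable sort on -rate keeps lower indices first among ties
    order = np.argsort(-rates, kind="stable")
    drop = set(order[:n].tolist())
    keep = [j for j in range(a.n_sites) if j not in drop]
    return a.take_sites(keep)


def mask_sites(a: Alignment, mask) -> Alignment:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (a.n_sites,):
        raise UsageError("mask must have one entry per alignment column")
    return a.take_sites(np.flatnonzero(mask))


def filter_sites(a: Alignment, mode: str, **kwargs) -> Alignment:
    """Dispatch on filtering mode: ``remove_constant_proportion(p)``,
    ``remove_fastest_n(n, rates)``, or ``mask(mask)``."""
    if mode == "remove_constant_proportion":
        return remove_constant_proportion(a, kwargs["p"])
    if mode == "remove_fastest_n":
        return remove_fastest_n(a, kwargs["n"], kwargs["rates"])
    if mode == "mask":
        return mask_sites(a, kwargs["mask"])
    raise UsageError(f"unknown filter mode {mode!r}")


# ---------------------------------------------------------------------------
# compositions

@dataclass
class CompositionTable:
    """Per-taxon counts of non-missing plain states (taxa x states)."""

    counts: pd.DataFrame  # index: labels, columns: alphabet states, int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def pooled(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def composition_counts(a: Alignment) -> CompositionTable:
    """Tabulate plain-state counts per taxon; ambiguity and missing
    characters are excluded."""
    states = list(a.alphabet.states)
    counts = np.zeros((a.n_taxa, len(states)), dtype=int)
    for k, s in enumerate(states):
        counts[:, k] = (a.matrix == s).sum(axis=1)
    return CompositionTable(pd.DataFrame(counts, index=list(a.labels), columns=states))
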