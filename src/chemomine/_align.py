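"""Dynamic-programming alignment kernels (numba-compiled).

Two kernels live here:

* an affine-gap Smith-Waterman over coded sequences with an arbitrary
  substitution matrix (used for both protein/protein and nucleotide/nucleotide
  local alignment in the search engine), with full traceback;

* a frameshift-aware local protein-to-DNA aligner that steps through the DNA in
  codons but allows 1-2 bp slips (frameshifts), in-frame codon indels, and
  read-through of stop codons.  Gene reconstruction and pseudogene calling are
  built on its traceback.

Gap costs follow the BLAST convention: a gap of length k costs open + k*extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .seqcore import CODON_TABLE

# ---------------------------------------------------------------------------
# alphabets / coding

PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
PROT_INDEX = {c: i for i, c in enumerate(PROT_ALPHABET)}
NUC_ALPHABET5 = "ACGTN"
NUC_INDEX = {c: i for i, c in enumerate(NUC_ALPHABET5)}

STOP_CODE = PROT_INDEX["*"]
X_CODE = PROT_INDEX["X"]


def _load_blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    alpha = str(m.alphabet)
    out = np.zeros((24, 24), dtype=np.int32)
    for i, a in enumerate(PROT_ALPHABET):
        for j, b in enumerate(PROT_ALPHABET):
            out[i, j] = int(m[alpha.index(a), alpha.index(b)])
    return out


BLOSUM62 = _load_blosum62()


def nuc_matrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    """5x5 scoring matrix over ACGTN; anything involving N scores `mismatch`."""
    m = np.full((5, 5), mismatch, dtype=np.int32)
    for i in range(4):
        m[i, i] = match
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return m


def encode_prot(residues: str) -> np.ndarray:
    return np.fromiter(
        (PROT_INDEX.get(c, X_CODE) for c in residues), dtype=np.int8, count=len(residues)
    )


def encode_nuc(residues: str) -> np.ndarray:
    return np.fromiter(
        (NUC_INDEX.get(c, 4) for c in residues), dtype=np.int8, count=len(residues)
    )


def _codon_aa_table() -> np.ndarray:
    """Map base-5 codon index (25*a + 5*b + c over ACGTN) to protein code."""
    tab = np.full(125, X_CODE, dtype=np.int8)
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            for k, c in enumerate("ACGT"):
                aa = CODON_TABLE[a + b + c]
                tab[25 * i + 5 * j + k] = PROT_INDEX[aa]
    return tab


CODON_AA = _codon_aa_table()

# ---------------------------------------------------------------------------
# Smith-Waterman, affine gaps, full traceback


@njit(cache=True)
def _sw_fill(a, b, sub, gap_open, gap_extend):
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in a (move along b)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in b (move along a)
    # pointers: 0 stop, 1 diag, 2 from E, 3 from F
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    eptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 open, 1 extend
    fptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    go = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo = H[i, j - 1] - go
            ee = E[i, j - 1] - gap_extend
            if ee > eo:
                E[i, j] = ee
                eptr[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - go
            fe = F[i - 1, j] - gap_extend
            if fe > fo:
                F[i, j] = fe
                fptr[i, j] = 1
            else:
                F[i, j] = fo
            d = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, eptr, fptr


def sw_align(a: np.ndarray, b: np.ndarray, sub: np.ndarray, gap_open: int, gap_extend: int):
    """Local alignment of coded sequences a vs b.

    Returns (score, a_start, a_end, b_start, b_end, n_identical, n_columns);
    coordinates half-open on each input. Score 0 means no positive alignment.
    """
    best, bi, bj, ptr, eptr, fptr = _sw_fill(
        a, b, sub, np.int32(gap_open), np.int32(gap_extend)
    )
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    i, j = bi, bj
    n_id = 0
    n_col = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                n_col += 1
                if a[i - 1] == b[j - 1]:
                    n_id += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_col += 1
            if eptr[i, j] == 0:
                state = 0
            j -= 1
        else:
            n_col += 1
            if fptr[i, j] == 0:
                state = 0
            i -= 1
    return int(best), int(i), int(bi), int(j), int(bj), n_id, n_col


@njit(cache=True)
def ungapped_extend(a, b, apos, bpos, seed_len, sub, xdrop):
    """X-drop ungapped extension of an exact seed at (apos, bpos); returns the
    best ungapped segment score through the seed."""
    score = 0
    for k in range(seed_len):
        score += sub[a[apos + k], b[bpos + k]]
    best = score
    run = score
    i, j = apos + seed_len, bpos + seed_len
    while i < len(a) and j < len(b):
        run += sub[a[i], b[j]]
        if run > best:
            best = run
        if run < best - xdrop:
            break
        i += 1
        j += 1
    left_best = 0
    run = 0
    i, j = apos - 1, bpos - 1
    while i >= 0 and j >= 0:
        run += sub[a[i], b[j]]
        if run > left_best:
            left_best = run
        if run < left_best - xdrop:
            break
        i -= 1
        j -= 1
    return best + left_best


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Score-only affine Smith-Waterman (linear memory)."""
    m, n = len(a), len(b)
    NEG = -(10**9)
    go = gap_open + gap_extend
    Hprev = np.zeros(n + 1, dtype=np.int32)
    Fprev = np.full(n + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        Hcur = np.zeros(n + 1, dtype=np.int32)
        Fcur = np.full(n + 1, NEG, dtype=np.int32)
        e = NEG
        for j in range(1, n + 1):
            eo = Hcur[j - 1] - go
            ee = e - gap_extend
            e = ee if ee > eo else eo
            fo = Hprev[j] - go
            fe = Fprev[j] - gap_extend
            f = fe if fe > fo else fo
            Fcur[j] = f
            h = Hprev[j - 1] + sub[a[i - 1], b[j - 1]]
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev = Hcur
        Fprev = Fcur
    return best


# ---------------------------------------------------------------------------
# frameshift-aware protein-to-DNA local alignment

# traceback move codes (stored in hptr):
#   0 stop; 1 codon (3 bp); 2 del1 (2 bp, 1-bp deletion); 3 del2 (1 bp, 2-bp
#   deletion); 4 ins1 (4 bp, 1-bp insertion); 5 ins2 (5 bp, 2-bp insertion);
#   6 from D (in-frame codon deletion, gap in DNA); 7 from I (extra codon in
#   DNA, gap in protein)
MOVE_DNA_STEP = {1: 3, 2: 2, 3: 1, 4: 4, 5: 5}


@njit(cache=True)
def _p2d_fill(prot, dna, sub, codon_aa, fs_pen, del_open, del_ext, ins_open, ins_ext):
    m = len(prot)
    n = len(dna)
    NEG = -(10**9)
    H = np.full((m + 1, n + 1), 0, dtype=np.int32)
    D = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    I = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    hptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    dptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    iptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        p = prot[i - 1]
        for j in range(n + 1):
            # D: protein residue unmatched, no DNA consumed (in-frame deletion)
            do = H[i - 1, j] - del_open
            de = D[i - 1, j] - del_ext
            if de > do:
                D[i, j] = de
                dptr[i, j] = 1
            else:
                D[i, j] = do
            # I: extra codon in DNA, no protein consumed
            if j >= 3:
                io = H[i, j - 3] - ins_open
                ie = I[i, j - 3] - ins_ext
                if ie > io:
                    I[i, j] = ie
                    iptr[i, j] = 1
                else:
                    I[i, j] = io
            h = 0
            mv = 0
            if j >= 3:
                c = codon_aa[25 * dna[j - 3] + 5 * dna[j - 2] + dna[j - 1]]
                v = H[i - 1, j - 3] + sub[p, c]
                if v > h:
                    h = v
                    mv = 1
                # 1-bp insertion: 4 bases consumed, score last 3 as the codon
                if j >= 4:
                    v = H[i - 1, j - 4] + sub[p, c] - fs_pen
                    if v > h:
                        h = v
                        mv = 4
                if j >= 5:
                    v = H[i - 1, j - 5] + sub[p, c] - fs_pen
                    if v > h:
                        h = v
                        mv = 5
            if j >= 2:
                v = H[i - 1, j - 2] - fs_pen
                if v > h:
                    h = v
                    mv = 2
            if j >= 1:
                v = H[i - 1, j - 1] - fs_pen
                if v > h:
                    h = v
                    mv = 3
            if D[i, j] > h:
                h = D[i, j]
                mv = 6
            if I[i, j] > h:
                h = I[i, j]
                mv = 7
            H[i, j] = h
            hptr[i, j] = mv
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, hptr, dptr, iptr


class P2DAlignment:
    """Traceback of a frameshift-aware protein-to-DNA local alignment.

    Attributes
    ----------
    score : int
    p_start, p_end : half-open span on the protein (consensus) that aligned
    d_start, d_end : half-open span on the DNA
    columns : list of (p_pos, d_pos, move) per protein residue consumed, in
        5'->3' order; move is a code from the kernel table; d_pos is the DNA
        offset of the first base consumed by that move (or the insertion point
        for in-frame deletions, move 6).
    inserted_codons : list of (p_pos, d_pos) for extra in-frame codons in DNA.
    """

    def __init__(self, score, p_start, p_end, d_start, d_end, columns, inserted):
        self.score = score
        self.p_start = p_start
        self.p_end = p_end
        self.d_start = d_start
        self.d_end = d_end
        self.columns = columns
        self.inserted_codons = inserted


def p2d_align(
    prot: np.ndarray,
    dna: np.ndarray,
    sub: np.ndarray = None,
    fs_pen: int = 14,
    del_open: int = 12,
    del_ext: int = 2,
    ins_open: int = 12,
    ins_ext: int = 2,
) -> P2DAlignment:
    if sub is None:
        sub = BLOSUM62
    best, bi, bj, hptr, dptr, iptr = _p2d_fill(
        prot, dna, sub, CODON_AA,
        np.int32(fs_pen), np.int32(del_open), np.int32(del_ext),
        np.int32(ins_open), np.int32(ins_ext),
    )
    columns = []
    inserted = []
    if best <= 0:
        return P2DAlignment(0, 0, 0, 0, 0, columns, inserted)
    i, j = bi, bj
    state = 0  # 0=H, 1=D, 2=I
    while True:
        if state == 0:
            mv = hptr[i, j]
            if mv == 0:
                break
            if mv in (1, 2, 3, 4, 5):
                step = MOVE_DNA_STEP[mv]
                columns.append((i - 1, j - step, int(mv)))
                i -= 1
                j -= step
            elif mv == 6:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns.append((i - 1, j, 6))
            if dptr[i, j] == 0:
                state = 0
            i -= 1
        else:
            inserted.append((i, j - 3))
            if iptr[i, j] == 0:
                state = 0
            j -= 3
    columns.reverse()
    inserted.reverse()
    return P2DAlignment(int(best), int(i), int(bi), int(j), int(bj), columns, inserted)
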