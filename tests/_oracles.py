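"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, no sklearn/scipy shortcuts) so it cannot share a code path with the
package under test.
"""

from __future__ import annotations

import math
import struct


# -- confusion-matrix metrics ------------------------------------------------

def confusion(y_true, y_pred):
    classes = sorted(set(list(y_true)) | set(list(y_pred)))
    idx = {c: i for i, c in enumerate(classes)}
    table = [[0] * len(classes) for _ in classes]
    for t, p in zip(y_true, y_pred):
        table[idx[t]][idx[p]] += 1
    return classes, table


def accuracy_oracle(y_true, y_pred):
    return sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)


def kappa_oracle(y_true, y_pred):
    classes, table = confusion(y_true, y_pred)
    n = len(y_true)
    p_o = sum(table[i][i] for i in range(len(classes))) / n
    p_e = 0.0
    for i in range(len(classes)):
        row = sum(table[i])
        col = sum(table[j][i] for j in range(len(classes)))
        p_e += (row * col) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def macro_f1_oracle(y_true, y_pred):
    classes = sorted(set(list(y_true)))
    f1s = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(f1s) / len(f1s)


def asr_oracle(y_pred, target):
    return sum(1 for p in y_pred if p == target) / len(y_pred)


def entropy_oracle(values):
    total = sum(values)
    h = 0.0
    for v in values:
        if v > 0:
            p = v / total
            h -= p * math.log(p)
    return h


# -- pure-Python SHA1 (independent of hashlib) -------------------------------

def _rotl(x, n):
    return ((x << n) | (x >> (32 - n))) & 0xFFFFFFFF


def sha1_oracle(data: bytes) -> str:
    h = [0x67452301, 0xEFCDAB89, 0x98BADCFE, 0x10325476, 0xC3D2E1F0]
    ml = len(data) * 8
    data = data + b"\x80" + b"\x00" * ((55 - len(data)) % 64) + struct.pack(">Q", ml)
    for off in range(0, len(data), 64):
        w = list(struct.unpack(">16I", data[off:off + 64]))
        for i in range(16, 80):
            w.append(_rotl(w[i - 3] ^ w[i - 8] ^ w[i - 14] ^ w[i - 16], 1))
        a, b, c, d, e = h
        for i in range(80):
            if i < 20:
                f, k = (b & c) | (~b & d), 0x5A827999
            elif i < 40:
                f, k = b ^ c ^ d, 0x6ED9EBA1
            elif i < 60:
                f, k = (b & c) | (b & d) | (c & d), 0x8F1BBCDC
            else:
                f, k = b ^ c ^ d, 0xCA62C1D6
            a, b, c, d, e = (
                (_rotl(a, 5) + f + e + k + w[i]) & 0xFFFFFFFF, a, _rotl(b, 30), c, d,
            )
        h = [(x + y) & 0xFFFFFFFF for x, y in zip(h, (a, b, c, d, e))]
    return "".join(f"{x:08x}" for x in h)
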