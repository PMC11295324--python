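"""GF(256) arithmetic and Reed-Solomon coding over primitive poly 0x11D.

The generator polynomial for ``n_ec`` check bytes has roots at
alpha^0 .. alpha^(n_ec - 1); decoding uses Berlekamp-Massey, Chien search
and Forney's algorithm and corrects up to floor(n_ec / 2) byte errors at
unknown positions.
"""

from __future__ import annotations

PRIMITIVE_POLY = 0x11D  # x^8 + x^4 + x^3 + x^2 + 1

# log/antilog tables; EXP is doubled so products index without a mod
EXP = [0] * 512
LOG = [0] * 256
_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= PRIMITIVE_POLY
for _i in range(255, 512):
    EXP[_i] = EXP[_i - 255]


class RSDecodeError(Exception):
    """Raised when the error count exceeds the code's correction capacity."""


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return EXP[LOG[a] + LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(256) division by zero")
    if a == 0:
        return 0
    return EXP[(LOG[a] - LOG[b]) % 255]


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0
    return EXP[(LOG[a] * n) % 255]


def gf_inv(a: int) -> int:
    return gf_div(1, a)


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    """Product of polynomials with coefficients highest degree first."""
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a == 0:
            continue
        for j, b in enumerate(q):
            out[i + j] ^= gf_mul(a, b)
    return out


def poly_eval(p: list[int], x: int) -> int:
    """Horner evaluation; coefficients highest degree first."""
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator_poly(n_ec: int) -> list[int]:
    """Monic generator with roots alpha^0 .. alpha^(n_ec-1), degree n_ec."""
    if n_ec < 1:
        raise ValueError("n_ec must be >= 1")
    g = [1]
    for i in range(n_ec):
        g = poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_ec_codewords(data, n_ec: int) -> list[int]:
    """The n_ec check bytes: remainder of data(x) * x^n_ec mod generator."""
    gen = rs_generator_poly(n_ec)
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        coef = rem[i]
        if coef != 0:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[-n_ec:]


def _syndromes(codeword: list[int], n_ec: int) -> list[int]:
    return [poly_eval(codeword, gf_pow(2, i)) for i in range(n_ec)]


def _berlekamp_massey(synd: list[int]) -> list[int]:
    """Error locator sigma(x), lowest degree first."""
    sigma = [1]
    prev = [1]
    m = 1
    b = 1
    for i, s in enumerate(synd):
        d = s
        for j in range(1, len(sigma)):
            if i - j >= 0:
                d ^= gf_mul(sigma[j], synd[i - j])
        if d == 0:
            m += 1
        elif 2 * (len(sigma) - 1) <= i:
            tmp = sigma[:]
            scale = gf_div(d, b)
            shifted = [0] * m + [gf_mul(scale, c) for c in prev]
            if len(shifted) > len(sigma):
                sigma = sigma + [0] * (len(shifted) - len(sigma))
            for k, c in enumerate(shifted):
                sigma[k] ^= c
            prev = tmp
            b = d
            m = 1
        else:
            scale = gf_div(d, b)
            shifted = [0] * m + [gf_mul(scale, c) for c in prev]
            if len(shifted) > len(sigma):
                sigma = sigma + [0] * (len(shifted) - len(sigma))
            for k, c in enumerate(shifted):
                sigma[k] ^= c
            m += 1
    while len(sigma) > 1 and sigma[-1] == 0:
        sigma.pop()
    return sigma


def rs_correct(codeword, n_ec: int) -> list[int]:
    """Correct up to floor(n_ec/2) byte errors in data+EC; returns data+EC.

    Raises :class:`RSDecodeError` when the word is not within correction
    distance of any codeword (detected via locator/syndrome inconsistency).
    """
    word = list(codeword)
    synd = _syndromes(word, n_ec)
    if not any(synd):
        return word
    sigma = _berlekamp_massey(synd)
    n_err = len(sigma) - 1
    if n_err == 0 or n_err > n_ec // 2:
        raise RSDecodeError("error count exceeds correction capacity")
    # Chien search: roots alpha^-p for error positions p (from the end)
    n = len(word)
    positions = []
    for p in range(n):
        x_inv = gf_pow(2, (255 - (n - 1 - p)) % 255)  # alpha^-(n-1-p)
        acc = 0
        for k, c in enumerate(sigma):
            acc ^= gf_mul(c, gf_pow(x_inv, k))
        if acc == 0:
            positions.append(p)
    if len(positions) != n_err:
        raise RSDecodeError("error locator degree does not match root count")
    # Forney: omega(x) = [S(x) sigma(x)] mod x^n_ec  (S lowest degree first)
    omega = [0] * n_ec
    for i in range(n_ec):
        acc = 0
        for j in range(min(i + 1, len(sigma))):
            acc ^= gf_mul(sigma[j], synd[i - j])
        omega[i] = acc
    sigma_deriv = [c if k % 2 == 1 else 0 for k, c in enumerate(sigma)][1:]
    for p in positions:
        x_inv = gf_pow(2, (255 - (n - 1 - p)) % 255)
        num = 0
        for k, c in enumerate(omega):
            num ^= gf_mul(c, gf_pow(x_inv, k))
        den = 0
        for k, c in enumerate(sigma_deriv):
            den ^= gf_mul(c, gf_pow(x_inv, k))
        if den == 0:
            raise RSDecodeError("Forney denominator vanished")
        # X_p factor because the generator's first root is alpha^0
        word[p] ^= gf_mul(gf_pow(2, n - 1 - p), gf_div(num, den))
    if any(_syndromes(word, n_ec)):
        raise RSDecodeError("residual syndromes after correction")
    return word
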