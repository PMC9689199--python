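import sympy as sp
import pytest

from sesm import EquationSpec


@pytest.fixture(scope="session")
def kdv_plus():
    """KdV with the +6uu_x convention (bilinear/Hirota form)."""
    return EquationSpec.from_text(
        "Derivative(u(x,t),t) + 6*u(x,t)*Derivative(u(x,t),x) + Derivative(u(x,t),x,x,x)",
        "u", ["x", "t"],
    )


@pytest.fixture(scope="session")
def kdv_minus():
    """KdV with the -6uu_x convention (negative soliton)."""
    return EquationSpec.from_text(
        "Derivative(u(x,t),t) - 6*u(x,t)*Derivative(u(x,t),x) + Derivative(u(x,t),x,x,x)",
        "u", ["x", "t"],
    )


@pytest.fixture(scope="session")
def fisher_ode():
    """Second-order quadratic reaction-diffusion traveling-wave ODE."""
    return EquationSpec.from_text(
        "nu1*Derivative(Q(xi),xi,xi) + nu2*Derivative(Q(xi),xi) + mu2*Q(xi)^2 + mu1*Q(xi)",
        "Q", ["xi"], parameters=["nu1", "nu2", "mu1", "mu2"],
    )
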