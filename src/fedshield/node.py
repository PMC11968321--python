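"""Simulated data-holding server.

A :class:`Node` owns read-only snapshot datasets, an account table with
user-specific data views, a disclosure-settings vector, and an append-only
audit log.  Every analyst command enters through :meth:`Node.dispatch`, which
runs the full invocation flow: session check → command parser → semantic
checks → pre-execution disclosure controls → execution → post-execution
output check.  Aggregate requests return low-dimensional payloads; assign
requests store a derived object server-side and return only a status message
(ok flag, object class, dimension validity) — never values.  Exactly one
audit event is appended per dispatch, whatever the outcome.

Nodes are in-process objects orchestrated by the client; network transport is
outside this simulation's scope.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import re
import uuid
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fedstats
from .audit import AuditLog, digest_args
from .errors import FedShieldError
from .filters import check_glm_dimension, check_levels, check_subset_size
from .obfuscation import gaussian_noise_obfuscate, knn_centroid_obfuscate
from .parser import Request, parse_and_validate
from .settings import (
    DisclosureSettings,
    FunctionRegistry,
    blocked_functions,
    default_registry,
    default_settings,
    settings_from_mapping,
    validate_settings,
)

__all__ = [
    "DataView",
    "Node",
    "Session",
    "SiteDataset",
    "StatusMessage",
    "UserAccount",
    "hash_token",
    "load_site_config",
]


def hash_token(token: str) -> str:
    return hashlib.sha256(token.encode()).hexdigest()


@dataclass(frozen=True)
class StatusMessage:
    """Non-disclosive acknowledgement of an assign: no values, ever."""

    ok: bool
    object_class: str = ""
    dims_valid: bool = True


@dataclass
class SiteDataset:
    """A site's snapshot table with declared column types.

    Columns are ``numeric`` or ``categorical``; a column whose values are all
    numeric is inferred numeric unless overridden.  Snapshots are never
    mutated — assigns create derived objects in a session workspace.
    """

    name: str
    table: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise FedShieldError("CONFIG_ERROR")
        for col in self.table.columns:
            if col not in self.types:
                self.types[col] = (
                    "numeric"
                    if pd.api.types.is_numeric_dtype(self.table[col])
                    else "categorical"
                )

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @staticmethod
    def from_csv(name: str, path, type_overrides: Mapping[str, str] | None = None) -> "SiteDataset":
        frame = pd.read_csv(path)
        return SiteDataset(name=name, table=frame, types=dict(type_overrides or {}))


@dataclass(frozen=True)
class DataView:
    """A user-specific permitted-variable projection of one dataset."""

    dataset: str
    permitted_variables: frozenset[str]


@dataclass(frozen=True)
class UserAccount:
    user: str
    token_hash: str
    views: tuple[DataView, ...] = ()
    profile: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.token_hash:
            raise FedShieldError("CONFIG_ERROR")


@dataclass
class Session:
    """One authenticated analyst session: per-session volatile workspace."""

    user: str
    site: str
    session_id: str
    settings: DisclosureSettings
    workspace: dict = field(default_factory=dict)


# ordering of strictness per settings field: +1 means larger is stricter
_STRICTNESS = {
    "tab_threshold": +1,
    "subset_threshold": +1,
    "glm_ratio": -1,
    "string_max": -1,
    "string_short_max": -1,
    "levels_density": -1,
    "levels_max": -1,
    "knn_min": +1,
    "noise_min_fraction": +1,
}


class Node:
    """One simulated data server."""

    def __init__(
        self,
        site: str,
        datasets: Sequence[SiteDataset],
        accounts: Sequence[UserAccount],
        settings: DisclosureSettings | None = None,
        registry: FunctionRegistry | None = None,
        custodian_token: str = "",
        clock=None,
        node_seed: int | None = None,
    ):
        self.site = site
        self.settings = settings if settings is not None else default_settings()
        verdict = validate_settings(self.settings)
        if not verdict.accepted:
            # invalid custodian settings abort node start; never fall back
            raise FedShieldError("CONFIG_ERROR")
        self.registry = registry if registry is not None else default_registry()
        self.datasets: dict[str, SiteDataset] = {}
        for ds in datasets:
            if ds.name in self.datasets:
                raise FedShieldError("CONFIG_ERROR")
            self.datasets[ds.name] = ds
        self.accounts: dict[str, UserAccount] = {}
        for acc in accounts:
            if acc.user in self.accounts:
                raise FedShieldError("CONFIG_ERROR")
            for view in acc.views:
                ds = self.datasets.get(view.dataset)
                if ds is None or not view.permitted_variables <= set(ds.table.columns):
                    raise FedShieldError("CONFIG_ERROR")
            self.accounts[acc.user] = acc
        self._custodian_token = custodian_token or uuid.uuid4().hex
        self.log = AuditLog(site, self._custodian_token, clock)
        self._rng = np.random.default_rng(node_seed)
        self._handlers = {
            "asNumericDS": self._h_as_numeric,
            "subsetDS": self._h_subset,
            "setSeedDS": self._h_set_seed,
            "tableDS": self._h_table,
            "summaryDS": self._h_summary,
            "levelsDS": self._h_levels,
            "glmShareDS": self._h_glm_share,
            "scatterPlotDS": self._h_scatter,
        }

    # -- authentication -----------------------------------------------------

    def login(self, user: str, token: str) -> Session:
        """Authenticate and open a fresh, empty workspace.

        Unknown user and wrong token produce the same error so account names
        cannot be enumerated.
        """
        account = self.accounts.get(user)
        if account is None or hash_token(token) != account.token_hash:
            raise FedShieldError("AUTH_FAILED")
        return Session(
            user=user,
            site=self.site,
            session_id=uuid.uuid4().hex[:12],
            settings=self._effective_settings(account),
        )

    def _effective_settings(self, account: UserAccount) -> DisclosureSettings:
        """Site settings, tightened (never loosened) by profile overrides."""
        s = self.settings
        profile = account.profile or {}
        overrides = profile.get("disclosure", {})
        if overrides:
            candidate = settings_from_mapping(
                {**_settings_keys(s), **overrides}, strict=True
            )
            updates = {}
            for fld, direction in _STRICTNESS.items():
                cur, new = getattr(s, fld), getattr(candidate, fld)
                if (direction > 0 and new >= cur) or (direction < 0 and new <= cur):
                    updates[fld] = new
            s = replace(s, **updates)
        level = profile.get("privacyControlLevel")
        if level is not None and blocked_functions(level) >= blocked_functions(s.privacy_level):
            s = replace(s, privacy_level=level)
        return s

    def export_log(self, credential: str):
        return self.log.export(credential)

    # -- views --------------------------------------------------------------

    def resolve_view(self, session: Session, dataset: str) -> pd.DataFrame:
        """Project the dataset onto the user's permitted variables.

        Row order is preserved; the result is a copy so the snapshot can
        never be mutated through it.
        """
        account = self.accounts.get(session.user)
        if account is None or session.site != self.site:
            raise FedShieldError("SESSION_INVALID")
        ds = self.datasets.get(dataset)
        if ds is None:
            raise FedShieldError("UNKNOWN_SYMBOL")
        for view in account.views:
            if view.dataset == dataset:
                cols = [c for c in ds.table.columns if c in view.permitted_variables]
                return ds.table.loc[:, cols].copy()
        raise FedShieldError("VIEW_DENIED")

    # -- dispatch -----------------------------------------------------------

    def dispatch(self, session: Session, r: Request):
        """Single entry point for every analyst command.

        Returns an aggregate payload or a :class:`StatusMessage`; raises a
        typed :class:`FedShieldError` otherwise.  Exactly one audit event is
        appended regardless of outcome.
        """
        meta: dict = {}
        outcome = "executed"
        try:
            try:
                return self._execute(session, r, meta)
            except FedShieldError as err:
                rule = meta.get("rule")
                outcome = f"blocked:{rule}" if rule else f"error:{err.code}"
                raise
            except Exception:
                outcome = "error:INTERNAL_ERROR"
                raise FedShieldError("INTERNAL_ERROR") from None
        finally:
            try:
                digest = digest_args(r.to_envelope())
            except Exception:
                digest = ""
            self.log.record(
                user=str(getattr(session, "user", "?")),
                session_id=str(getattr(session, "session_id", "?")),
                function=str(getattr(r, "function", "?")),
                kind=str(getattr(r, "kind", "?")),
                arg_digest=digest,
                predicate=str(meta.get("predicate", "")),
                outcome=outcome,
                metadata=meta,
            )

    def _execute(self, session: Session, r: Request, meta: dict):
        if (
            not isinstance(session, Session)
            or session.site != self.site
            or session.user not in self.accounts
        ):
            raise FedShieldError("SESSION_INVALID")
        verdict = parse_and_validate(r, self.registry, session.settings)
        if not verdict.accepted:
            meta["parser_reasons"] = list(verdict.codes())
            raise FedShieldError("PARSE_REJECTED")
        entry = self.registry.get(r.function)
        if entry is None or not entry.implemented:
            raise FedShieldError("NOT_IMPLEMENTED")
        handler = self._handlers.get(r.function)
        if handler is None:
            raise FedShieldError("NOT_IMPLEMENTED")
        return handler(session, r, meta)

    # -- symbol resolution --------------------------------------------------

    def _resolve_table(self, session: Session, name: str) -> pd.DataFrame:
        if name in session.workspace:
            obj = session.workspace[name]
            if not isinstance(obj, pd.DataFrame):
                raise FedShieldError("SEMANTIC_ERROR")
            return obj
        if name in self.datasets:
            return self.resolve_view(session, name)
        raise FedShieldError("UNKNOWN_SYMBOL")

    def _resolve_vector(self, session: Session, symbol: str) -> tuple[pd.Series, str]:
        """Resolve ``table.column`` or a workspace vector; returns (values, type)."""
        if "." in symbol:
            root, col = symbol.split(".", 1)
            if root in session.workspace:
                table = session.workspace[root]
                if not isinstance(table, pd.DataFrame) or col not in table.columns:
                    raise FedShieldError("UNKNOWN_SYMBOL")
                return table[col], self._column_type(root, col, table)
            if root in self.datasets:
                ds = self.datasets[root]
                if col not in ds.table.columns:
                    raise FedShieldError("UNKNOWN_SYMBOL")
                view = self.resolve_view(session, root)
                if col not in view.columns:
                    raise FedShieldError("VARIABLE_DENIED")
                return view[col], ds.types[col]
            raise FedShieldError("UNKNOWN_SYMBOL")
        if symbol in session.workspace:
            obj = session.workspace[symbol]
            if isinstance(obj, pd.Series):
                kind = "numeric" if pd.api.types.is_numeric_dtype(obj) else "categorical"
                return obj, kind
        raise FedShieldError("UNKNOWN_SYMBOL")

    def _column_type(self, root: str, col: str, table: pd.DataFrame) -> str:
        # derived workspace tables inherit source dataset types when known
        for ds in self.datasets.values():
            if col in ds.types and col in ds.table.columns:
                return ds.types[col]
        return "numeric" if pd.api.types.is_numeric_dtype(table[col]) else "categorical"

    # -- handlers -----------------------------------------------------------

    @staticmethod
    def _arg_values(r: Request, kinds: Sequence[str]):
        if len(r.args) != len(kinds) or any(
            a.kind != k for a, k in zip(r.args, kinds)
        ):
            raise FedShieldError("SEMANTIC_ERROR")
        return [a.value for a in r.args]

    def _h_as_numeric(self, session, r, meta):
        (symbol,) = self._arg_values(r, ["symbol"])
        vec, _ = self._resolve_vector(session, symbol)
        coerced = pd.to_numeric(vec, errors="coerce")
        session.workspace[r.target] = coerced
        meta.update({"source": symbol, "target": r.target, "class": "numeric"})
        return StatusMessage(ok=True, object_class="numeric", dims_valid=True)

    def _h_subset(self, session, r, meta):
        source, predicate = self._arg_values(r, ["symbol", "string"])
        return self.assign_subset(session, source, predicate, r.target, session.settings, meta)

    def assign_subset(
        self,
        session: Session,
        source: str,
        predicate: str,
        target: str,
        s: DisclosureSettings,
        meta: dict | None = None,
    ) -> StatusMessage:
        """Create a predicate-defined subset iff it meets the size threshold.

        The resulting size is recorded in the custodian-side audit metadata;
        the analyst-facing rejection never states it.
        """
        meta = meta if meta is not None else {}
        table = self._resolve_table(session, source)
        mask = _evaluate_predicate(table, predicate)
        size = int(mask.sum())
        meta.update({"source": source, "target": target, "predicate": predicate, "subset_size": size})
        decision = check_subset_size(size, s)
        if not decision.allowed:
            meta["rule"] = decision.rule
            raise FedShieldError("SUBSET_TOO_SMALL")
        session.workspace[target] = table.loc[mask].copy()
        return StatusMessage(ok=True, object_class="data.frame", dims_valid=True)

    def _h_set_seed(self, session, r, meta):
        (seed,) = self._arg_values(r, ["number"])
        session.workspace["_seed"] = int(seed)
        meta["seed_set"] = True
        return StatusMessage(ok=True, object_class="integer", dims_valid=True)

    def _h_table(self, session, r, meta):
        if not 1 <= len(r.args) <= 3 or any(a.kind != "symbol" for a in r.args):
            raise FedShieldError("SEMANTIC_ERROR")
        symbols = [a.value for a in r.args]
        columns = {}
        names = []
        for sym in symbols:
            vec, kind = self._resolve_vector(session, sym)
            if kind != "categorical":
                raise FedShieldError("SEMANTIC_ERROR")
            name = sym.split(".", 1)[-1]
            columns[name] = vec.reset_index(drop=True)
            names.append(name)
        frame = pd.DataFrame(columns)
        meta.update({"source": symbols[0], "variables": names})
        try:
            table = fedstats.site_contingency(frame, names, session.settings)
        except FedShieldError as err:
            if err.code == "LEVELS_BLOCKED":
                meta["rule"] = "nfilter.levels"
            raise
        meta["dims"] = [len(lv) for lv in table.levels]
        meta["suppressed"] = table.suppressed
        return table

    def _h_summary(self, session, r, meta):
        (symbol,) = self._arg_values(r, ["symbol"])
        vec, kind = self._resolve_vector(session, symbol)
        if kind != "numeric":
            raise FedShieldError("SEMANTIC_ERROR")
        meta["source"] = symbol
        try:
            share = fedstats.site_summary(vec, session.settings)
        except FedShieldError as err:
            if err.code == "SUMMARY_TOO_SMALL":
                meta["rule"] = "nfilter.subset"
            raise
        meta["N"] = share.N
        return share

    def _h_levels(self, session, r, meta):
        (symbol,) = self._arg_values(r, ["symbol"])
        vec, kind = self._resolve_vector(session, symbol)
        if kind != "categorical":
            raise FedShieldError("SEMANTIC_ERROR")
        levels = tuple(sorted(map(str, vec.dropna().unique())))
        meta.update({"source": symbol, "n_levels": len(levels)})
        decision = check_levels(len(levels), max(len(vec), 1), session.settings)
        if not decision.allowed:
            meta["rule"] = decision.rule
            raise FedShieldError("LEVELS_BLOCKED")
        return levels

    def _h_glm_share(self, session, r, meta):
        source, formula, family, beta = self._arg_values(
            r, ["symbol", "string", "string", "vector"]
        )
        model = fedstats.parse_formula(formula, family)
        table = self._resolve_table(session, source)
        for name in (model.outcome, *model.covariates):
            if name not in table.columns:
                raise FedShieldError(
                    "UNKNOWN_SYMBOL"
                    if name not in self._dataset_columns(source)
                    else "VARIABLE_DENIED"
                )
        data = table.loc[:, [model.outcome, *model.covariates]].apply(
            pd.to_numeric, errors="coerce"
        )
        data = data.dropna()
        n_obs = len(data)
        if n_obs < 1:
            raise FedShieldError("SEMANTIC_ERROR")
        meta.update({"source": source, "formula": formula, "family": family, "N": n_obs})
        decision = check_glm_dimension(model.p, n_obs, session.settings)
        if not decision.allowed:
            meta["rule"] = decision.rule
            raise FedShieldError("GLM_DIM_BLOCKED")
        y = data[model.outcome].to_numpy(dtype=float)
        cols = [np.ones(n_obs)] if model.intercept else []
        cols += [data[c].to_numpy(dtype=float) for c in model.covariates]
        X = np.column_stack(cols)
        beta_arr = np.asarray(list(beta), dtype=float)
        if beta_arr.shape != (model.p,):
            raise FedShieldError("SEMANTIC_ERROR")
        return fedstats.glm_share(X, y, beta_arr, family)

    def _dataset_columns(self, source: str) -> set[str]:
        ds = self.datasets.get(source)
        return set(ds.table.columns) if ds is not None else set()

    def _h_scatter(self, session, r, meta):
        args = list(r.args)
        symbols = [a.value for a in itertools.takewhile(lambda a: a.kind == "symbol", args)]
        rest = args[len(symbols):]
        if not 1 <= len(symbols) <= 2 or not rest or rest[0].kind != "string":
            raise FedShieldError("SEMANTIC_ERROR")
        method = rest[0].value
        numbers = [a.value for a in rest[1:]]
        if any(a.kind != "number" for a in rest[1:]) or not 1 <= len(numbers) <= 2:
            raise FedShieldError("SEMANTIC_ERROR")
        param = numbers[0]
        explicit_seed = int(numbers[1]) if len(numbers) > 1 else None

        series = []
        for sym in symbols:
            vec, kind = self._resolve_vector(session, sym)
            if kind != "numeric":
                raise FedShieldError("SEMANTIC_ERROR")
            series.append(pd.to_numeric(vec, errors="coerce").reset_index(drop=True))
        frame = pd.concat(series, axis=1).dropna()
        points = frame.to_numpy(dtype=float)
        meta.update({"source": symbols[0], "method": method, "n_points": len(points)})

        if method == "knn":
            try:
                result = knn_centroid_obfuscate(points, int(param), session.settings)
            except FedShieldError as err:
                if err.code == "OBFUSCATION_BLOCKED":
                    meta["rule"] = "nfilter.kNN"
                raise
            return result
        if method == "noise":
            if points.shape[1] != 1:
                raise FedShieldError("SEMANTIC_ERROR")
            seed, seed_source = self._noise_seed(session, explicit_seed)
            meta.update({"seed": seed, "seed_source": seed_source})
            try:
                result = gaussian_noise_obfuscate(
                    points[:, 0], float(param), seed, session.settings
                )
            except FedShieldError as err:
                if err.code == "OBFUSCATION_BLOCKED":
                    meta["rule"] = "nfilter.noise"
                raise
            return result
        raise FedShieldError("SEMANTIC_ERROR")

    def _noise_seed(self, session: Session, explicit: int | None) -> tuple[int, str]:
        """Analyst seed control is honoured only where setSeedDS is permitted;
        otherwise the node draws its own seed (logged custodian-side only)."""
        seed_allowed = "setSeedDS" not in blocked_functions(session.settings.privacy_level)
        candidate = explicit if explicit is not None else session.workspace.get("_seed")
        if seed_allowed and candidate is not None:
            return int(candidate), "analyst"
        return int(self._rng.integers(2**31)), "node"


def _settings_keys(s: DisclosureSettings) -> dict:
    from .settings import settings_to_mapping

    return settings_to_mapping(s)


# ---------------------------------------------------------------------------
# predicate evaluation
# ---------------------------------------------------------------------------

_COMPARISON = re.compile(
    r"^\s*([A-Za-z_][A-Za-z0-9._]*)\s*(<=|>=|==|!=|<|>)\s*([-+0-9.eE']+|\"[^\"]*\"|'[^']*')\s*$"
)


def _evaluate_predicate(table: pd.DataFrame, predicate: str) -> pd.Series:
    """Evaluate ``var op constant`` atoms combined with ``&`` and ``|``.

    ``&`` binds tighter than ``|``; comparisons against missing values are
    False.  The grammar is deliberately tiny — predicates arrive as parser-
    validated opaque strings and are interpreted only here.
    """
    if not predicate.strip():
        raise FedShieldError("SEMANTIC_ERROR")
    or_terms = predicate.split("|")
    result = pd.Series(False, index=table.index)
    for or_term in or_terms:
        and_mask = pd.Series(True, index=table.index)
        for atom in or_term.split("&"):
            and_mask &= _evaluate_atom(table, atom)
        result |= and_mask
    return result


def _evaluate_atom(table: pd.DataFrame, atom: str) -> pd.Series:
    m = _COMPARISON.match(atom)
    if not m:
        raise FedShieldError("SEMANTIC_ERROR")
    name, op, raw = m.groups()
    if name not in table.columns:
        raise FedShieldError("UNKNOWN_SYMBOL")
    col = table[name]
    if raw.startswith(("'", '"')):
        value: object = raw[1:-1]
        series = col.astype(str).where(col.notna())
    else:
        try:
            value = float(raw)
        except ValueError:
            raise FedShieldError("SEMANTIC_ERROR") from None
        series = pd.to_numeric(col, errors="coerce")
    ops = {
        "<": series.lt,
        "<=": series.le,
        ">": series.gt,
        ">=": series.ge,
        "==": series.eq,
        "!=": series.ne,
    }
    mask = ops[op](value)
    return mask.fillna(False).astype(bool) & col.notna()


# ---------------------------------------------------------------------------
# site configuration files
# ---------------------------------------------------------------------------


def load_site_config(path) -> Node:
    """Build a node from a YAML or JSON site config file.

    Layout::

        site: siteA
        custodian_token: "..."
        data: {D: siteA.csv}
        column_types: {D: {smoker: categorical}}
        disclosure: {nfilter.tab: 3, datashield.privacyControlLevel: banana}
        accounts:
          - user: alice
            token_sha256: <hex>
            views: [{dataset: D, variables: [age, bmi]}]

    CSV paths are resolved relative to the config file.  Invalid disclosure
    overrides abort node construction.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    try:
        site = cfg["site"]
        datasets = []
        overrides = cfg.get("column_types", {})
        for name, csv_rel in cfg.get("data", {}).items():
            csv_path = path.parent / csv_rel
            datasets.append(SiteDataset.from_csv(name, csv_path, overrides.get(name)))
        accounts = []
        for acc in cfg.get("accounts", []):
            views = tuple(
                DataView(v["dataset"], frozenset(v["variables"])) for v in acc.get("views", [])
            )
            accounts.append(
                UserAccount(
                    user=acc["user"],
                    token_hash=acc["token_sha256"],
                    views=views,
                    profile=acc.get("profile"),
                )
            )
        settings = settings_from_mapping(cfg.get("disclosure", {}), strict=True)
        node_seed = cfg.get("node_seed")
    except (KeyError, TypeError, ValueError) as err:
        raise FedShieldError("CONFIG_ERROR") from err
    return Node(
        site=site,
        datasets=datasets,
        accounts=accounts,
        settings=settings,
        custodian_token=cfg.get("custodian_token", ""),
        node_seed=node_seed,
    )
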