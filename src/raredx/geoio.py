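"""Read/write the pipeline's on-disk formats.

Cases, survey respondents and network nodes travel as headered CSV (UTF-8);
census units, clinics and road segments travel as GeoJSON FeatureCollections
(Point centroids / anchors, LineString segments).  All coordinates are
planar metres; any projection from geographic coordinates is expected to
happen before data reaches this layer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape

from .access import Clinic, Node, RoadSegment, TurnPenaltyTable
from .config import AGE_DECADES
from .errors import DataError
from .prevalence import CaseRecord, CensusUnit
from .survey import SurveyRespondent

_CASE_FLAGS = ("deceased", "address_missing", "out_of_study_area", "geocode_failed")


# ---------------------------------------------------------------- nodes CSV

def write_nodes_csv(nodes: Sequence[Node], path) -> None:
    pd.DataFrame([{"node_id": n.node_id, "x": n.x, "y": n.y,
                   "elevation_m": n.elevation_m} for n in nodes]
                 ).to_csv(path, index=False, float_format="%.17g")


def read_nodes_csv(path) -> list[Node]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [Node(str(r.node_id), float(r.x), float(r.y), float(r.elevation_m))
            for r in df.itertuples()]


# ------------------------------------------------------------ roads GeoJSON

def write_roads_geojson(segments: Sequence[RoadSegment], nodes: Sequence[Node], path) -> None:
    xy = {n.node_id: (n.x, n.y) for n in nodes}
    features = []
    for s in segments:
        geom = LineString([xy[s.from_node], xy[s.to_node]])
        features.append({
            "type": "Feature", "geometry": mapping(geom),
            "properties": {"segment_id": s.segment_id, "from_node": s.from_node,
                           "to_node": s.to_node, "length_m": s.length_m,
                           "speed_kmh": s.speed_kmh, "road_class": s.road_class,
                           "oneway": s.oneway}})
    _dump_fc(features, path)


def read_roads_geojson(path) -> list[RoadSegment]:
    segs = []
    for props, _geom in _load_fc(path):
        segs.append(RoadSegment(
            segment_id=str(props["segment_id"]), from_node=str(props["from_node"]),
            to_node=str(props["to_node"]), length_m=float(props["length_m"]),
            speed_kmh=float(props["speed_kmh"]), road_class=str(props["road_class"]),
            oneway=str(props.get("oneway", "both"))))
    return segs


# ------------------------------------------------------------ units GeoJSON

def write_units_geojson(units: Sequence[CensusUnit], path) -> None:
    features = []
    for u in units:
        props = {"unit_id": u.unit_id, "unit_type": u.unit_type,
                 "in_cma": u.in_cma, "name": u.name}
        for d in AGE_DECADES:
            props[f"pop_{d.replace('-', '_').replace('+', 'plus')}"] = \
                int(u.population_by_decade.get(d, 0))
        features.append({"type": "Feature",
                         "geometry": mapping(Point(u.centroid)),
                         "properties": props})
    _dump_fc(features, path)


def read_units_geojson(path) -> list[CensusUnit]:
    units = []
    for props, geom in _load_fc(path):
        pops = {}
        for d in AGE_DECADES:
            key = f"pop_{d.replace('-', '_').replace('+', 'plus')}"
            pops[d] = int(props.get(key, 0))
        units.append(CensusUnit(
            unit_id=str(props["unit_id"]), unit_type=str(props.get("unit_type", "CSD")),
            centroid=(geom.x, geom.y), population_by_decade=pops,
            in_cma=bool(props.get("in_cma", False)), name=str(props.get("name", ""))))
    return units


# ---------------------------------------------------------- clinics GeoJSON

def write_clinics_geojson(clinics: Sequence[Clinic], path) -> None:
    features = [{"type": "Feature", "geometry": mapping(Point(c.x, c.y)),
                 "properties": {"clinic_id": c.clinic_id, "node_id": c.node_id}}
                for c in clinics]
    _dump_fc(features, path)


def read_clinics_geojson(path) -> list[Clinic]:
    return [Clinic(clinic_id=str(p["clinic_id"]), node_id=str(p["node_id"]),
                   x=g.x, y=g.y) for p, g in _load_fc(path)]


# ----------------------------------------------------------------- CSV data

def write_cases_csv(cases: Sequence[CaseRecord], path) -> None:
    rows = []
    for c in cases:
        row = {"patient_id": c.patient_id, "region_code": c.region_code,
               "age_years": c.age_years}
        row.update({f: int(getattr(c, f)) for f in _CASE_FLAGS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cases_csv(path) -> list[CaseRecord]:
    df = pd.read_csv(path)
    required = {"patient_id", "region_code", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cases file {path} missing columns {sorted(missing)}")
    cases = []
    for r in df.itertuples():
        flags = {f: bool(getattr(r, f, 0)) for f in _CASE_FLAGS}
        cases.append(CaseRecord(patient_id=str(r.patient_id),
                                region_code=str(r.region_code),
                                age_years=int(r.age_years), **flags))
    return cases


def write_survey_csv(respondents: Sequence[SurveyRespondent], path) -> None:
    rows = []
    for r in respondents:
        rows.append({
            "respondent_id": r.respondent_id, "physician_dx": int(r.physician_dx),
            "age_now": r.age_now, "age_dx": r.age_dx, "female": int(r.female),
            "north_american": int(r.north_american), "epistaxis": int(r.epistaxis),
            "ent_consult_before_dx": int(r.ent_consult_before_dx),
            "age_first_ent": r.age_first_ent if r.age_first_ent is not None else "",
            "er_consult_before_dx": int(r.er_consult_before_dx),
            "age_first_er": r.age_first_er if r.age_first_er is not None else ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey_csv(path) -> list[SurveyRespondent]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        def _opt(v):
            return None if pd.isna(v) else float(v)
        out.append(SurveyRespondent(
            respondent_id=str(r.respondent_id), physician_dx=bool(r.physician_dx),
            age_now=float(r.age_now), age_dx=float(r.age_dx), female=bool(r.female),
            north_american=bool(r.north_american), epistaxis=bool(r.epistaxis),
            ent_consult_before_dx=bool(r.ent_consult_before_dx),
            age_first_ent=_opt(r.age_first_ent),
            er_consult_before_dx=bool(r.er_consult_before_dx),
            age_first_er=_opt(r.age_first_er)))
    return out


def write_penalties_csv(penalties: TurnPenaltyTable, path) -> None:
    rows = [{"maneuver": m, "road_class": c, "seconds": s}
            for (m, c), s in sorted(penalties.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_penalties_csv(path, allow_out_of_range: bool = False) -> TurnPenaltyTable:
    df = pd.read_csv(path)
    table = {(str(r.maneuver), str(r.road_class)): float(r.seconds)
             for r in df.itertuples()}
    return TurnPenaltyTable(table, allow_out_of_range=allow_out_of_range)


# ------------------------------------------------------------------ helpers

def _dump_fc(features: list[dict], path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}),
        encoding="utf-8")


def _load_fc(path):
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") != "FeatureCollection":
        raise DataError(f"{path} is not a GeoJSON FeatureCollection")
    for feat in data.get("features", []):
        yield feat.get("properties", {}), shape(feat["geometry"])
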