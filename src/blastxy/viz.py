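"""Rendering: the three-plot Graph layout, static (SVG) and interactive (HTML).

The Graph page is a main x,y panel (one horizontal track per replicon,
0-360 degrees along x) plus two overview selectors — a bottom panel for
choosing an x sub-range across all replicons and a right panel for
choosing a y sub-range of replicons.  Overview panels draw density
summaries (result counts per bin: 360 x-bins, one y-bin per replicon)
rather than every mark, so they stay responsive at the 50 k display cap.

A result is *visible* in a view when any part of its gene vector
intersects the x range (not only its dot), so long genes do not vanish
when their origin sits just outside a zoomed window.  Hovering a mark
shows the relative position, BitScore, query header, organism and gene
product; clicking reveals the full record in the text box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import matplotlib
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.figure import Figure

from .model import FULL_CIRCLE_DEG, PlottedResult, Replicon
from .projection import DARK_BLUE, YELLOW, bitscore_to_color, ColorScale

#: Named zoom preset: a convenient x-window for browsing gene clusters.
DEFAULT_ZOOM_DEG = 25.0

# fixed marker style constants; the alignment segment is the "thicker
# line over the vector"
DOT_SIZE_PT = 4.0
VECTOR_WIDTH_PT = 1.0
SEGMENT_WIDTH_PT = 3.0

_CMAP = LinearSegmentedColormap.from_list(
    "bitscore", [tuple(c / 255 for c in YELLOW), tuple(c / 255 for c in DARK_BLUE)]
)

HOVER_FIELDS = ("relative_position", "bitscore", "query", "organism", "product")
CLICK_EXTRA_FIELDS = ("subject_id", "replicon_id", "evalue", "s_start", "s_end")


@dataclass(frozen=True)
class ViewSpec:
    """A rectangular window onto the plot: degrees x replicon indices."""

    x_range: Tuple[float, float] = (0.0, FULL_CIRCLE_DEG)
    y_range: Tuple[int, int] = (1, 10**9)
    show_vectors: bool = True
    show_segments: bool = True

    def __post_init__(self) -> None:
        if self.x_range[0] > self.x_range[1]:
            raise ValueError(f"inverted x_range {self.x_range}")
        if self.y_range[0] > self.y_range[1]:
            raise ValueError(f"inverted y_range {self.y_range}")
        if self.x_range[0] < 0 or self.x_range[1] > FULL_CIRCLE_DEG:
            raise ValueError(f"x_range {self.x_range} outside [0, 360]")


def vector_intervals(r: PlottedResult) -> List[Tuple[float, float]]:
    """Degree interval(s) covered by a result's vector, split at 360/0."""
    if r.vector_deg >= 0:
        lo, hi = r.x, r.x + r.vector_deg
    else:
        lo, hi = r.x + r.vector_deg, r.x
    if lo >= 0 and hi <= FULL_CIRCLE_DEG:
        return [(lo, hi)]
    # origin-wrapping vector: split into the two arcs
    if hi > FULL_CIRCLE_DEG:
        return [(lo, FULL_CIRCLE_DEG), (0.0, hi - FULL_CIRCLE_DEG)]
    return [(lo + FULL_CIRCLE_DEG, FULL_CIRCLE_DEG), (0.0, hi)]


def select_view(
    rows: Sequence[PlottedResult], view: ViewSpec
) -> List[PlottedResult]:
    """Rows whose vector intersects the x range and whose y is in range."""
    x0, x1 = view.x_range
    y0, y1 = view.y_range
    out = []
    for r in rows:
        if not (y0 <= r.y <= y1):
            continue
        if any(hi >= x0 and lo <= x1 for lo, hi in vector_intervals(r)):
            out.append(r)
    return out


def hover_payload(r: PlottedResult) -> dict:
    """The pop-up text shown on mouseover of a result."""
    return {
        "relative_position": r.x,
        "bitscore": r.bitscore,
        "query": r.query_id,
        "organism": r.organism,
        "product": r.product,
    }


def click_payload(r: PlottedResult) -> dict:
    """The fuller record shown in the text box when a result is clicked."""
    payload = hover_payload(r)
    payload.update(
        subject_id=r.subject_id,
        replicon_id=r.replicon_id,
        evalue=r.evalue,
        s_start=r.s_start,
        s_end=r.s_end,
    )
    return payload


def _directed_points(
    r: PlottedResult, offset_deg: float, length_deg: float
) -> Tuple[List[float], List[float]]:
    """Polyline (with NaN breaks at the 360/0 seam) for a stretch of the
    vector starting ``offset_deg`` from the dot, ``length_deg`` long."""
    sign = 1.0 if r.vector_deg >= 0 else -1.0
    a = r.x + sign * offset_deg
    b = r.x + sign * (offset_deg + length_deg)
    lo, hi = min(a, b), max(a, b)
    xs: List[float] = []
    ys: List[float] = []
    pieces: List[Tuple[float, float]] = []
    if lo >= 0 and hi <= FULL_CIRCLE_DEG:
        pieces = [(lo, hi)]
    elif hi > FULL_CIRCLE_DEG:
        pieces = [(lo, FULL_CIRCLE_DEG), (0.0, hi - FULL_CIRCLE_DEG)]
    else:
        pieces = [(lo + FULL_CIRCLE_DEG, FULL_CIRCLE_DEG), (0.0, hi)]
    for i, (p, q) in enumerate(pieces):
        if i:
            xs.append(float("nan"))
            ys.append(float("nan"))
        xs.extend([p, q])
        ys.extend([r.y, r.y])
    return xs, ys


def render_static(
    rows: Sequence[PlottedResult],
    view: ViewSpec,
    path: str,
    scale: ColorScale | None = None,
    title: str = "",
) -> List[PlottedResult]:
    """Render the three-plot layout to a deterministic SVG.

    One dot + one vector polyline + one (thicker, bitscore-colored)
    alignment-segment polyline per visible result, tagged with
    ``dot-i`` / ``vector-i`` / ``segment-i`` ids in the SVG tree.
    Returns the visible rows that were drawn.
    """
    visible = select_view(rows, view)
    if scale is None:
        scale = ColorScale.from_results([r.bitscore for r in rows])
    y_max = max([r.y for r in rows], default=1)
    y0, y1 = max(1, view.y_range[0]), min(y_max, view.y_range[1])
    with matplotlib.rc_context({"svg.hashsalt": "blastxy"}):
        fig = Figure(figsize=(10, 6))
        gs = fig.add_gridspec(
            2, 2, width_ratios=[12, 1], height_ratios=[6, 1],
            hspace=0.25, wspace=0.08,
        )
        ax = fig.add_subplot(gs[0, 0])
        ax_y = fig.add_subplot(gs[0, 1], sharey=ax)
        ax_x = fig.add_subplot(gs[1, 0], sharex=ax)
        for i, r in enumerate(visible):
            _, rgb = bitscore_to_color(r.bitscore, scale)
            color = tuple(c / 255 for c in rgb)
            ax.plot(
                [r.x], [r.y], marker="o", linestyle="none", color=color,
                markersize=DOT_SIZE_PT, gid=f"dot-{i}",
            )
            if view.show_vectors:
                xs, ys = _directed_points(r, 0.0, abs(r.vector_deg))
                ax.plot(
                    xs, ys, color="0.4", linewidth=VECTOR_WIDTH_PT,
                    gid=f"vector-{i}", solid_capstyle="butt",
                )
            if view.show_segments:
                xs, ys = _directed_points(r, r.seg_offset_deg, r.seg_len_deg)
                ax.plot(
                    xs, ys, color=color, linewidth=SEGMENT_WIDTH_PT,
                    gid=f"segment-{i}", solid_capstyle="butt",
                )
        ax.set_xlim(view.x_range)
        ax.set_ylim(y0 - 0.5, y1 + 0.5)
        ax.set_xlabel("relative position (degrees)")
        ax.set_ylabel("replicon")
        if title:
            ax.set_title(title)
        # overview densities: 360 x-bins over all rows, one y-bin per replicon
        xs_all = [r.x for r in rows]
        ax_x.hist(xs_all, bins=360, range=(0, FULL_CIRCLE_DEG), color="0.5")
        ax_x.set_yticks([])
        ax_x.set_xlabel("x overview (degrees)")
        counts: dict = {}
        for r in rows:
            counts[r.y] = counts.get(r.y, 0) + 1
        ax_y.barh(
            list(counts.keys()), list(counts.values()), color="0.5", height=0.8
        )
        ax_y.set_xticks([])
        ax_y.tick_params(labelleft=False)
        ax_y.set_title("y", fontsize=8)
        sm = matplotlib.cm.ScalarMappable(
            cmap=_CMAP,
            norm=matplotlib.colors.Normalize(
                scale.min_bitscore, max(scale.max_bitscore, scale.min_bitscore + 1e-9)
            ),
        )
        fig.colorbar(sm, ax=ax_y, label="BitScore", fraction=0.5, pad=0.3)
        fig.savefig(path, format="svg", metadata={"Date": None})
    return visible


def results_data_json(rows: Sequence[PlottedResult]) -> str:
    """Canonical JSON serialization of the embedded data island
    (identical schema to the results array of the results JSON)."""
    return json.dumps([r.to_dict() for r in rows], separators=(",", ":"))


def render_interactive(
    rows: Sequence[PlottedResult],
    view: ViewSpec,
    path: str,
    replicons: Sequence[Replicon] = (),
    title: str = "Graph",
) -> List[PlottedResult]:
    """Write a single-file interactive HTML Graph page.

    The page embeds the capped result set as a JSON data island and
    renders it client-side: the main panel supports zoom (wheel) and
    drag, the bottom/right overview panels support range selection,
    mouseover shows the hover payload and click fills the text box with
    the full record.  Returns the rows embedded.
    """
    visible = select_view(rows, view)
    data_json = results_data_json(list(rows))
    rep_json = json.dumps(
        [
            {
                "replicon_id": r.replicon_id,
                "organism": r.organism,
                "replicon_index": r.replicon_index,
            }
            for r in replicons
        ],
        separators=(",", ":"),
    )
    view_json = json.dumps(
        {"x0": view.x_range[0], "x1": view.x_range[1],
         "y0": view.y_range[0], "y1": view.y_range[1]},
        separators=(",", ":"),
    )
    html = _GRAPH_TEMPLATE.replace("__TITLE__", _escape(title))
    html = html.replace("__DATA__", data_json)
    html = html.replace("__REPLICONS__", rep_json)
    html = html.replace("__VIEW__", view_json)
    with open(path, "w") as fh:
        fh.write(html)
    return visible


def render_table_html(
    rows: Sequence[PlottedResult], path: str, title: str = "Table"
) -> None:
    """Write the spreadsheet-style Table page (sortable, "contains"
    filterable per column) as a single HTML file."""
    data_json = results_data_json(list(rows))
    html = _TABLE_TEMPLATE.replace("__TITLE__", _escape(title))
    html = html.replace("__DATA__", data_json)
    with open(path, "w") as fh:
        fh.write(html)


def _escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


_GRAPH_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>__TITLE__</title>
<style>
body{font-family:sans-serif;margin:12px}
#layout{display:grid;grid-template-columns:820px 90px;grid-gap:6px}
canvas{border:1px solid #999;background:#fff}
#tooltip{position:absolute;display:none;background:#ffe;border:1px solid #886;
padding:4px 6px;font-size:12px;pointer-events:none;white-space:pre}
#detail{border:1px solid #999;padding:6px;margin-top:6px;font-size:13px;
min-height:3em;white-space:pre-wrap}
</style></head><body>
<h2>__TITLE__</h2>
<div id="layout">
<canvas id="main" width="820" height="460"></canvas>
<canvas id="yov" width="90" height="460"></canvas>
<canvas id="xov" width="820" height="80"></canvas>
</div>
<div id="tooltip"></div>
<div id="detail">Click a result to see its full record.</div>
<script type="application/json" id="blastxy-data">__DATA__</script>
<script type="application/json" id="blastxy-replicons">__REPLICONS__</script>
<script type="application/json" id="blastxy-view">__VIEW__</script>
<script>
"use strict";
const DATA=JSON.parse(document.getElementById("blastxy-data").textContent);
const REPS=JSON.parse(document.getElementById("blastxy-view")?
  document.getElementById("blastxy-replicons").textContent:"[]");
const V=JSON.parse(document.getElementById("blastxy-view").textContent);
const yMax=DATA.reduce((m,d)=>Math.max(m,d.y),1);
let view={x0:V.x0,x1:V.x1,y0:Math.max(1,V.y0),y1:Math.min(yMax,V.y1)};
const main=document.getElementById("main"),mc=main.getContext("2d");
const xov=document.getElementById("xov"),xc=xov.getContext("2d");
const yov=document.getElementById("yov"),yc=yov.getContext("2d");
const tip=document.getElementById("tooltip");
const bsMin=DATA.reduce((m,d)=>Math.min(m,d.bitscore),Infinity);
const bsMax=DATA.reduce((m,d)=>Math.max(m,d.bitscore),-Infinity);
function colorOf(d){const v=(bsMax>bsMin)?(d.bitscore-bsMin)/(bsMax-bsMin):1;
  const r=Math.round(255*(1-v)),g=Math.round(255*(1-v)),b=Math.round(139*v);
  return "rgb("+r+","+g+","+b+")";}
function px(x){return (x-view.x0)/(view.x1-view.x0)*main.width;}
function py(y){return main.height-(y-view.y0+0.5)/(view.y1-view.y0+1)*main.height;}
function drawMain(){
  mc.clearRect(0,0,main.width,main.height);
  for(const d of DATA){
    if(d.y<view.y0||d.y>view.y1)continue;
    const s=Math.sign(d.vector_deg)||1;
    const lo=Math.min(d.x,d.x+d.vector_deg),hi=Math.max(d.x,d.x+d.vector_deg);
    if(hi<view.x0||lo>view.x1)continue;
    const Y=py(d.y);
    mc.strokeStyle="#666";mc.lineWidth=1;
    mc.beginPath();mc.moveTo(px(lo),Y);mc.lineTo(px(hi),Y);mc.stroke();
    mc.strokeStyle=colorOf(d);mc.lineWidth=3;
    const a=d.x+s*d.seg_offset_deg,b=d.x+s*(d.seg_offset_deg+d.seg_len_deg);
    mc.beginPath();mc.moveTo(px(Math.min(a,b)),Y);mc.lineTo(px(Math.max(a,b)),Y);mc.stroke();
    mc.fillStyle=colorOf(d);
    mc.beginPath();mc.arc(px(d.x),Y,3,0,6.2832);mc.fill();
  }
}
function drawXov(sel){
  xc.clearRect(0,0,xov.width,xov.height);
  const bins=new Array(360).fill(0);
  for(const d of DATA)bins[Math.min(359,Math.floor(d.x))]++;
  const mx=Math.max(1,...bins);
  xc.fillStyle="#888";
  for(let i=0;i<360;i++){const h=bins[i]/mx*(xov.height-4);
    xc.fillRect(i/360*xov.width,xov.height-h,xov.width/360,h);}
  xc.fillStyle="rgba(60,100,200,0.3)";
  xc.fillRect(view.x0/360*xov.width,0,(view.x1-view.x0)/360*xov.width,xov.height);
}
function drawYov(){
  yc.clearRect(0,0,yov.width,yov.height);
  const cnt={};for(const d of DATA)cnt[d.y]=(cnt[d.y]||0)+1;
  const mx=Math.max(1,...Object.values(cnt));
  yc.fillStyle="#888";
  for(const y in cnt){const w=cnt[y]/mx*(yov.width-4);
    const Y=yov.height-(y/(yMax+1))*yov.height;
    yc.fillRect(0,Y-3,w,6);}
  yc.fillStyle="rgba(60,100,200,0.3)";
  const yA=yov.height-(view.y1/(yMax+1))*yov.height;
  const yB=yov.height-((view.y0-1)/(yMax+1))*yov.height;
  yc.fillRect(0,yA,yov.width,yB-yA);
}
function redraw(){drawMain();drawXov();drawYov();}
function nearest(mx,my){
  let best=null,bd=64;
  for(const d of DATA){
    if(d.y<view.y0||d.y>view.y1)continue;
    const dx=px(d.x)-mx,dy=py(d.y)-my,dd=dx*dx+dy*dy;
    if(dd<bd){bd=dd;best=d;}
  }
  return best;
}
main.addEventListener("mousemove",ev=>{
  const r=main.getBoundingClientRect();
  const d=nearest(ev.clientX-r.left,ev.clientY-r.top);
  if(d){
    tip.style.display="block";
    tip.style.left=(ev.pageX+12)+"px";tip.style.top=(ev.pageY+12)+"px";
    tip.textContent="relative position: "+d.x.toFixed(2)+
      "\\nBitScore: "+d.bitscore+"\\nquery: "+d.query_id+
      "\\norganism: "+d.organism+"\\nproduct: "+d.product;
  }else tip.style.display="none";
});
main.addEventListener("mouseleave",()=>{tip.style.display="none";});
main.addEventListener("click",ev=>{
  const r=main.getBoundingClientRect();
  const d=nearest(ev.clientX-r.left,ev.clientY-r.top);
  if(d)document.getElementById("detail").textContent=
    "relative position: "+d.x.toFixed(4)+"  BitScore: "+d.bitscore+
    "\\nquery: "+d.query_id+"  subject: "+d.subject_id+
    "\\norganism: "+d.organism+"  replicon: "+d.replicon_id+
    "\\nproduct: "+d.product+
    "\\nE-value: "+d.evalue+"  subject coords: "+d.s_start+".."+d.s_end;
});
main.addEventListener("wheel",ev=>{
  ev.preventDefault();
  const f=ev.deltaY<0?0.8:1.25;
  const r=main.getBoundingClientRect();
  const cx=view.x0+(ev.clientX-r.left)/main.width*(view.x1-view.x0);
  view.x0=Math.max(0,cx-(cx-view.x0)*f);
  view.x1=Math.min(360,cx+(view.x1-cx)*f);
  redraw();
});
let drag=null;
main.addEventListener("mousedown",ev=>{drag={x:ev.clientX,x0:view.x0,x1:view.x1};});
window.addEventListener("mouseup",()=>{drag=null;xsel=null;ysel=null;});
main.addEventListener("mousemove",ev=>{
  if(!drag)return;
  const dx=(drag.x-ev.clientX)/main.width*(drag.x1-drag.x0);
  let a=drag.x0+dx,b=drag.x1+dx;
  if(a<0){b-=a;a=0;}if(b>360){a-=b-360;b=360;}
  view.x0=a;view.x1=b;redraw();
});
let xsel=null;
xov.addEventListener("mousedown",ev=>{
  const r=xov.getBoundingClientRect();
  xsel=(ev.clientX-r.left)/xov.width*360;
});
xov.addEventListener("mousemove",ev=>{
  if(xsel===null)return;
  const r=xov.getBoundingClientRect();
  const x=(ev.clientX-r.left)/xov.width*360;
  view.x0=Math.max(0,Math.min(xsel,x));
  view.x1=Math.min(360,Math.max(xsel,x));
  redraw();
});
let ysel=null;
yov.addEventListener("mousedown",ev=>{
  const r=yov.getBoundingClientRect();
  ysel=(1-(ev.clientY-r.top)/yov.height)*(yMax+1);
});
yov.addEventListener("mousemove",ev=>{
  if(ysel===null)return;
  const r=yov.getBoundingClientRect();
  const y=(1-(ev.clientY-r.top)/yov.height)*(yMax+1);
  view.y0=Math.max(1,Math.round(Math.min(ysel,y)));
  view.y1=Math.min(yMax,Math.round(Math.max(ysel,y)));
  redraw();
});
redraw();
</script></body></html>
"""

_TABLE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>__TITLE__</title>
<style>
body{font-family:sans-serif;margin:12px}
table{border-collapse:collapse;font-size:13px}
th,td{border:1px solid #bbb;padding:2px 6px}
th{cursor:pointer;background:#eef}
input{width:95%;font-size:11px}
</style></head><body>
<h2>__TITLE__</h2>
<table id="tbl"><thead>
<tr id="heads"></tr><tr id="filters"></tr>
</thead><tbody id="body"></tbody></table>
<script type="application/json" id="blastxy-data">__DATA__</script>
<script>
"use strict";
const DATA=JSON.parse(document.getElementById("blastxy-data").textContent);
const COLS=[["Query","query_id"],["Subject","subject_id"],
 ["Organism","organism"],["Replicon","replicon_id"],["RelPosition","x"],
 ["BitScore","bitscore"],["Evalue","evalue"],["Product","product"]];
const TEXT=new Set(["query_id","subject_id","organism","replicon_id","product"]);
let rows=DATA.slice(),sortCol=null,sortDir=1;
const needles={};
const heads=document.getElementById("heads");
const filters=document.getElementById("filters");
for(const [name,attr] of COLS){
  const th=document.createElement("th");th.textContent=name;
  th.onclick=()=>{sortDir=(sortCol===attr)?-sortDir:1;sortCol=attr;render();};
  heads.appendChild(th);
  const tf=document.createElement("th");
  if(TEXT.has(attr)){
    const inp=document.createElement("input");
    inp.placeholder="contains...";
    inp.oninput=()=>{needles[attr]=inp.value;render();};
    tf.appendChild(inp);
  }
  filters.appendChild(tf);
}
function render(){
  rows=DATA.filter(d=>Object.entries(needles).every(
    ([a,n])=>!n||String(d[a]).includes(n)));
  if(sortCol)rows=rows.slice().sort((p,q)=>{
    const a=p[sortCol],b=q[sortCol];
    return (a<b?-1:a>b?1:0)*sortDir;});
  const body=document.getElementById("body");
  body.innerHTML="";
  for(const d of rows){
    const tr=document.createElement("tr");
    for(const [,attr] of COLS){
      const td=document.createElement("td");
      let v=d[attr];
      if(attr==="x")v=v.toFixed(4);
      td.textContent=v;tr.appendChild(td);
    }
    body.appendChild(tr);
  }
}
render();
</script></body></html>
"""
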