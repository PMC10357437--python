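"""One-off generator for the packaged TSV fixtures (run from repo root)."""
import csv, pathlib

DATA = pathlib.Path("src/strokemir/data")

# (study_id, pmid, author, year, country, specimen, n_case, n_control, technique, [(mirna, dir)])
STUDIES = [
 ("tan2009", 19888324, "Tan, K. S.", 2009, "Singapore", "whole_blood", 19, 5, "microarray, qRT-PCR",
  [("hsa-miR-126-3p","down"),("hsa-miR-144-3p","up"),("hsa-miR-16-5p","up"),
   ("hsa-miR-21-5p","up"),("hsa-miR-223-3p","up"),("hsa-miR-320a-3p","up")]),
 ("zengl2011", 21622133, "Zeng, L.", 2011, "China", "whole_blood", 112, 60, "qRT-PCR",
  [("hsa-miR-210-3p","down")]),
 ("long2013", 24237608, "Long, G.", 2013, "China", "plasma", 38, 50, "qRT-PCR",
  [("hsa-miR-126-3p","down"),("hsa-miR-30a-5p","down")]),
 ("jickling2014", 24911610, "Jickling, G. C.", 2014, "USA", "pbmc", 24, 24, "microarray, qRT-PCR",
  [("hsa-let-7i-5p","down"),("hsa-miR-122-5p","down"),("hsa-miR-148a-3p","down"),
   ("hsa-miR-19a-3p","down"),("hsa-miR-320d","down"),("hsa-miR-363-3p","up"),
   ("hsa-miR-4429","down"),("hsa-miR-487b-3p","up")]),
 ("liu2015", 25257664, "Liu, Y.", 2015, "China", "serum", 31, 11, "qRT-PCR",
  [("hsa-miR-124-3p","down"),("hsa-miR-9-5p","down")]),
 ("wangw2014", 25287657, "Wang, W.", 2014, "China", "plasma", 136, 116, "microarray, qRT-PCR",
  [("hsa-miR-106b-5p","up"),("hsa-miR-320d","down"),("hsa-miR-320e","down"),("hsa-miR-4306","up")]),
 ("lip2015", 25410304, "Li, P.", 2015, "China", "serum", 117, 82, "microarray, qRT-PCR",
  [("hsa-miR-1246","up"),("hsa-miR-1299","up"),("hsa-miR-1913","down"),("hsa-miR-224-3p","down"),
   ("hsa-miR-3149","up"),("hsa-miR-32-3p","up"),("hsa-miR-377-5p","down"),("hsa-miR-423-5p","up"),
   ("hsa-miR-451a","up"),("hsa-miR-4739","up"),("hsa-miR-518b","down"),("hsa-miR-532-5p","down")]),
 ("lis2015", 26044809, "Li, S.", 2015, "China", "whole_blood", 60, 30, "microarray, qRT-PCR",
  [("hsa-miR-146a-5p","down"),("hsa-miR-185-5p","down")]),
 ("jia2015", 26096228, "Jia, L.", 2015, "China", "serum", 146, 96, "qRT-PCR",
  [("hsa-miR-145-5p","up"),("hsa-miR-221-3p","down"),("hsa-miR-23a-3p","down")]),
 ("zengy2015", 26459744, "Zeng, Y.", 2015, "China", "serum", 10, 10, "qRT-PCR",
  [("hsa-miR-124-3p","down"),("hsa-miR-218-5p","down"),("hsa-miR-22-3p","up"),
   ("hsa-miR-23a-3p","up"),("hsa-miR-30a-5p","down"),("hsa-miR-33a-5p","down"),
   ("hsa-miR-330-3p","down"),("hsa-miR-9-5p","down")]),
 ("wu2015", 26885038, "Wu, J.", 2015, "China", "serum", 106, 120, "qRT-PCR",
  [("hsa-miR-15a-5p","up"),("hsa-miR-16-5p","up"),("hsa-miR-17-5p","up")]),
 ("liang2016", 27545688, "Liang, T.", 2016, "China", "plasma", 102, 97, "qRT-PCR",
  [("hsa-miR-34a-5p","up")]),
 ("huang2016", 27776139, "Huang, S.", 2016, "China", "whole_blood", 302, 302, "qRT-PCR",
  [("hsa-let-7e-5p","up")]),
 ("wangy2017", 28111007, "Wang, Y.", 2017, "China", "serum", 68, 39, "qRT-PCR",
  [("hsa-miR-221-3p","down"),("hsa-miR-382-5p","down")]),
 ("bam2018", 28168424, "Bam, M.", 2018, "USA", "pbmc", 19, 20, "microarray, qRT-PCR",
  [("hsa-miR-130a-3p","up"),("hsa-miR-320a","up"),("hsa-miR-376c-3p","up"),
   ("hsa-miR-432-5p","up"),("hsa-miR-4656","up"),("hsa-miR-487","up"),
   ("hsa-miR-503-5p","up"),("hsa-miR-874-3p","down")]),
 ("jin2017", 28875333, "Jin, F.", 2017, "China", "plasma", 106, 110, "qRT-PCR",
  [("hsa-miR-126-3p","down"),("hsa-miR-130a-3p","down"),("hsa-miR-185-5p","up"),
   ("hsa-miR-218-5p","up"),("hsa-miR-222-3p","up"),("hsa-miR-378a-5p","down")]),
 ("chen2018", 29402769, "Chen, Z.", 2018, "China", "serum", 128, 102, "qRT-PCR",
  [("hsa-miR-146b-5p","up")]),
 ("vijayan2018", 29701837, "Vijayan, M.", 2018, "USA", "serum", 34, 11, "Illumina deep sequencing, qRT-PCR",
  [("hsa-miR-122-5p","up"),("hsa-miR-211-5p","up"),("hsa-miR-22-3p","down"),
   ("hsa-miR-23a-3p","down"),("hsa-miR-30d-5p","down")]),
 ("jin2018", 30030634, "Jin, F.", 2018, "China", "plasma", 148, 148, "qRT-PCR",
  [("hsa-miR-126-3p","down"),("hsa-miR-130a-3p","down"),("hsa-miR-185-5p","up"),
   ("hsa-miR-219-5p","up"),("hsa-miR-222-3p","up")]),
 ("yoo2019", 30112629, "Yoo, H.", 2019, "Korea", "whole_blood", 10, 11, "microarray, TaqMan miRNA assay",
  [("hsa-let-7e-5p","up"),("hsa-miR-1229-3p","up"),("hsa-miR-1238-5p","up"),("hsa-miR-1270","up"),
   ("hsa-miR-1294","up"),("hsa-miR-1301-3p","up"),("hsa-miR-140-5p","down"),("hsa-miR-142-3p","down"),
   ("hsa-miR-144-3p","down"),("hsa-miR-186-5p","down"),("hsa-miR-18b-5p","down"),
   ("hsa-miR-19a-3p","down"),("hsa-miR-301a-3p","down"),("hsa-miR-32-5p","down"),
   ("hsa-miR-335-5p","down"),("hsa-miR-340-5p","down"),("hsa-miR-362-3p","down"),
   ("hsa-miR-505-5p","up"),("hsa-miR-517b-3p","down"),("hsa-miR-544a","up"),
   ("hsa-miR-579-3p","down"),("hsa-miR-628-5p","up"),("hsa-miR-660-5p","down"),
   ("hsa-miR-664a-5p","up"),("hsa-miR-877-5p","up")]),
 ("vankralingen2019", 30617992, "van Kralingen, J. C.", 2019, "UK", "serum", 139, 34, "microarray, qRT-PCR",
  [("hsa-miR-17-5p","up"),("hsa-miR-20b-5p","up"),("hsa-miR-27b-3p","up"),("hsa-miR-93-5p","up")]),
 ("giordano2019", 30678250, "Giordano, M.", 2019, "Italy", "serum", 18, 20, "qRT-PCR",
  [("hsa-miR-195-5p","up"),("hsa-miR-451a","up")]),
 ("geng2019", 30899379, "Geng, W.", 2019, "China", "plasma", 13, 17, "qRT-PCR",
  [("hsa-miR-126-3p","down")]),
 ("kotb2019", 31496785, "Kotb, H. G.", 2019, "Egypt", "serum", 44, 22, "qRT-PCR",
  [("hsa-miR-146a-5p","down")]),
 ("lil2020", 31935511, "Li, L.", 2020, "China", "whole_blood", 279, 279, "microarray, qRT-PCR",
  [("hsa-miR-1275","down")]),
 ("lis2020", 32406219, "Li, S.", 2020, "China", "serum", 80, 60, "qRT-PCR",
  [("hsa-miR-128-3p","up")]),
 ("guo2022", 35018114, "Guo, C.", 2022, "China", "serum", 142, 50, "qRT-PCR",
  [("hsa-miR-185-5p","up"),("hsa-miR-424-5p","up")]),
 ("aldous2022", 35328807, "Aldous, E. K.", 2022, "Qatar", "serum", 47, 96, "RNA-sequencing",
  [("hsa-miR-451a","up"),("hsa-miR-574-5p","down"),("hsa-miR-4446-3p","down"),
   ("hsa-miR-142-3p","down"),("hsa-miR-6721-5p","down"),("hsa-miR-676-3p","down"),
   ("hsa-miR-379-5p","down"),("hsa-miR-485-3p","down"),("hsa-miR-411-5p","down"),
   ("hsa-miR-149-5p","down")]),
 ("eyileten2022", 35562921, "Eyileten, C.", 2022, "Poland", "plasma", 28, 35, "qRT-PCR",
  [("hsa-miR-19a-3p","up"),("hsa-let-7f-5p","down")]),
]

SPECIAL_ALIASES = {
    # mature-name merges reconciling reported spellings with miRBase v22 mature names
    "hsa-miR-487": "hsa-miR-487b-3p",
    "hsa-miR-320a-3p": "hsa-miR-320a",
    "hsa-miR-219-5p": "hsa-miR-218-5p",
    # bare validation-assay names
    "hsa-miR-185": "hsa-miR-185-5p",
    "hsa-miR-218": "hsa-miR-218-5p",
    "hsa-miR-222": "hsa-miR-222-3p",
    "hsa-miR-487b": "hsa-miR-487b-3p",
    "hsa-miR-9": "hsa-miR-9-5p",
    "hsa-miR-124": "hsa-miR-124-3p",
}

# Table 3: target, (stroke mean, stroke sem), (healthy mean, healthy sem), n=20 each
TABLE3 = [
 ("hsa-let-7e-5p",   0.582, 0.143, -5e-04, 0.164),
 ("hsa-miR-17-5p",   0.509, 0.147,  0.0025, 0.135),
 ("hsa-miR-185-5p",  0.87,  0.221, -0.004, 0.139),
 ("hsa-miR-218-5p", -0.0685,0.273,  0.002, 0.244),
 ("hsa-miR-222-3p",  0.244, 0.123, -5e-04, 0.247),
 ("hsa-miR-451a",   -0.756, 0.243, -0.0025,0.359),
 ("hsa-miR-487b-3p",-0.693, 0.157,  0.001, 0.332),
 ("hsa-miR-9-5p",    0.138, 0.301, -5e-04, 0.163),
 ("hsa-miR-124-3p", -0.552, 0.207,  0.0035,0.168),
 ("hsa-miR-221-3p",  0.0055,0.197,  0.0035,0.248),
 ("hsa-miR-126-3p",  0.064, 0.356,  0.0025,0.185),
 ("hsa-miR-130a-3p", 0.592, 0.34,  -0.001, 0.316),
]

def main():
    DATA.mkdir(parents=True, exist_ok=True)
    with open(DATA / "catalog.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["study_id","pmid","first_author","year","country","specimen",
                    "n_case","n_control","technique","mirna_reported","direction"])
        for sid,pmid,auth,yr,country,spec,nc,nh,tech,mirs in STUDIES:
            for name,dirn in mirs:
                w.writerow([sid,pmid,auth,yr,country,spec,nc,nh,tech,name,dirn])
    names = sorted({m for *_ , mirs in STUDIES for m,_ in mirs} | set(SPECIAL_ALIASES))
    with open(DATA / "aliases.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reported_name","canonical_name"])
        for n in names:
            w.writerow([n, SPECIAL_ALIASES.get(n, n)])
    with open(DATA / "validation_summaries.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target","group","mean","sem","n"])
        for t, ms, ss, mh, sh in TABLE3:
            w.writerow([t,"stroke",ms,ss,20])
            w.writerow([t,"healthy",mh,sh,20])
    n_rows = sum(len(m) for *_, m in STUDIES)
    print(f"{len(STUDIES)} studies, {n_rows} report rows, {len(names)} alias entries")

if __name__ == "__main__":
    main()
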