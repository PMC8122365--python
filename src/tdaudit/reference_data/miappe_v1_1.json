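{
  "version": "1.1",
  "description": "MIAPPE (Minimal Information About a Plant Phenotyping Experiment) v1.1 concept model: the eleven concepts with their attributes and obligation levels. Attributes whose obligation the checklist leaves conditional are marked optional (conservative coverage scoring).",
  "concepts": {
    "investigation": {
      "attributes": {
        "investigation unique id": false,
        "investigation title": true,
        "investigation description": false,
        "submission date": false,
        "public release date": false,
        "license": false,
        "miappe version": true,
        "associated publication": false
      }
    },
    "study": {
      "attributes": {
        "study unique id": true,
        "study title": true,
        "study description": false,
        "start date of study": true,
        "end date of study": false,
        "contact institution": true,
        "geographic location (country)": true,
        "experimental site name": true,
        "geographic location (latitude)": false,
        "geographic location (longitude)": false,
        "geographic location (altitude)": false,
        "description of the experimental design": true,
        "type of growth facility": true,
        "description of growth facility": false,
        "observation unit level hierarchy": false,
        "observation unit description": true,
        "cultural practices": false,
        "map of experimental design": false
      }
    },
    "person": {
      "attributes": {
        "person name": true,
        "person email": false,
        "person id": false,
        "person role": true,
        "person affiliation": true
      }
    },
    "data file": {
      "attributes": {
        "data file link": true,
        "data file description": true,
        "data file version": true
      }
    },
    "biological material": {
      "attributes": {
        "biological material id": true,
        "organism": true,
        "genus": false,
        "species": false,
        "infraspecific name": false,
        "biological material latitude": false,
        "biological material longitude": false,
        "biological material altitude": false,
        "biological material coordinates uncertainty": false,
        "biological material preprocessing": false,
        "material source id": false,
        "material source doi": false,
        "material source description": false
      }
    },
    "environment": {
      "attributes": {
        "environment parameter": true,
        "environment parameter value": true
      }
    },
    "experimental factor": {
      "attributes": {
        "experimental factor type": true,
        "experimental factor description": false,
        "experimental factor values": true
      }
    },
    "event": {
      "attributes": {
        "event type": true,
        "event accession number": false,
        "event description": false,
        "event date": true
      }
    },
    "observation unit": {
      "attributes": {
        "observation unit id": true,
        "observation unit type": true,
        "observation unit external id": false,
        "spatial distribution": false,
        "observation unit factor value": false
      }
    },
    "sample": {
      "attributes": {
        "sample id": true,
        "plant structure development stage": true,
        "plant anatomical entity": true,
        "sample description": false,
        "collection date": true,
        "external id": false
      }
    },
    "observed variable": {
      "attributes": {
        "variable id": true,
        "variable name": true,
        "variable accession number": false,
        "trait": true,
        "trait accession number": false,
        "method": true,
        "method accession number": false,
        "method description": false,
        "reference associated to the method": false,
        "scale": true,
        "scale accession number": false,
        "time scale": false
      }
    }
  }
}
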